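"""Degenerate-primer arithmetic, in-silico PCR and database coverage.

IUPAC degeneracy codes (including inosine, ``I``) are expanded per position.
Inosine pairs with any template base and, following the convention used when
counting primer variants, contributes a factor of one to the degeneracy of a
primer (it is a single synthesized base, not a mixture).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from . import formats

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
    "I": frozenset("ACGT"),  # inosine: universal pairing
}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A", "U": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N", "I": "I",
}


@dataclass(frozen=True)
class Primer:
    name: str
    iupac_sequence: str
    orientation: str  # "forward" | "reverse"

    def __post_init__(self):
        seq = self.iupac_sequence.upper()
        if not seq:
            raise ValueError(f"primer {self.name}: empty sequence")
        bad = set(seq) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"primer {self.name}: invalid symbols {sorted(bad)}")
        if self.orientation not in {"forward", "reverse"}:
            raise ValueError(f"primer {self.name}: orientation must be forward/reverse")
        object.__setattr__(self, "iupac_sequence", seq)

    def __len__(self) -> int:
        return len(self.iupac_sequence)

    def reverse_complement(self) -> str:
        return "".join(_COMPLEMENT[c] for c in reversed(self.iupac_sequence))


def degeneracy(primer: Primer | str) -> int:
    """Number of distinct concrete oligonucleotides a degenerate primer encodes.

    Product over positions of the IUPAC set size, with inosine counting 1.
    """
    seq = primer.iupac_sequence if isinstance(primer, Primer) else primer.upper()
    total = 1
    for c in seq:
        if c not in IUPAC_SETS:
            raise ValueError(f"invalid IUPAC symbol {c!r}")
        total *= 1 if c == "I" else len(IUPAC_SETS[c])
    return total


def _mismatches(primer_seq: str, window: str) -> int:
    n = 0
    for p, t in zip(primer_seq, window):
        pset = IUPAC_SETS[p]
        tset = IUPAC_SETS.get(t)
        if tset is None or not (pset & tset):
            n += 1
    return n


def find_sites(template_nt: str, primer: Primer, max_mismatch: int = 1) -> list[int]:
    """0-based start positions where the primer anneals on the template.

    A forward primer is matched as printed on the given strand; a reverse
    primer is matched as its reverse complement (i.e. the positions returned
    are where the primed strand's binding site lies on this template).
    Template ambiguity codes count as a match when the primer's and the
    template's base sets intersect.
    """
    template = template_nt.upper()
    seq = primer.iupac_sequence if primer.orientation == "forward" else primer.reverse_complement()
    L = len(seq)
    return [
        i
        for i in range(len(template) - L + 1)
        if _mismatches(seq, template[i : i + L]) <= max_mismatch
    ]


@dataclass(frozen=True)
class PcrProduct:
    start: int          # 0-based start of the inter-primer sequence
    end: int            # exclusive end
    sequence: str       # inter-primer sequence (primers excluded)
    strand: str = "+"

    def __len__(self) -> int:
        return len(self.sequence)


def _pcr_one_strand(template: str, fwd: Primer, rev: Primer, max_mismatch: int,
                    max_product: int, strand: str) -> list[PcrProduct]:
    products = []
    fwd_sites = find_sites(template, fwd, max_mismatch)
    rev_sites = find_sites(template, rev, max_mismatch)
    for f in fwd_sites:
        ins_start = f + len(fwd)
        for r in rev_sites:
            if r < ins_start:
                continue
            if r - ins_start > max_product:
                continue
            products.append(
                PcrProduct(ins_start, r, template[ins_start:r], strand=strand)
            )
    return products


def in_silico_pcr(
    template_nt: str,
    fwd: Primer,
    rev: Primer,
    max_mismatch: int = 1,
    max_product: int = 5000,
    both_strands: bool = False,
) -> list[PcrProduct]:
    """Enumerate amplification products; lengths exclude both primers.

    Valid products have the forward site 5' of the reverse site (reverse
    primer annealing on the opposite strand).  Products longer than
    ``max_product`` are suppressed.  With ``both_strands`` the reverse
    complement of the template is scanned as well.
    """
    template = template_nt.upper()
    products = _pcr_one_strand(template, fwd, rev, max_mismatch, max_product, "+")
    if both_strands:
        rc = formats.reverse_complement(template)
        products += _pcr_one_strand(rc, fwd, rev, max_mismatch, max_product, "-")
    products.sort(key=lambda p: (p.strand, p.start, p.end))
    return products


def coverage(
    references: dict[str, str],
    fwd: Primer,
    rev: Primer,
    max_mismatch: int = 1,
    max_product: int = 5000,
) -> float:
    """Fraction of unique nucleotide references yielding >=1 product."""
    if not references:
        raise ValueError("empty reference database")
    unique = set(references.values())
    n_amplified = sum(
        1
        for seq in unique
        if in_silico_pcr(seq, fwd, rev, max_mismatch, max_product, both_strands=True)
    )
    return n_amplified / len(unique)


@dataclass
class TrimResult:
    kept: list[formats.Read]
    discarded: int


def trim_primers(
    reads: Iterable[formats.Read],
    fwd: Primer,
    rev: Primer,
    max_mismatch: int = 1,
) -> TrimResult:
    """Strip the 5' forward and 3' reverse primer sites off merged reads.

    Reads lacking a recognizable forward site at the 5' end or reverse site
    at the 3' end are discarded and tallied.  Kept reads carry no residual
    primer, so re-trimming the retained inserts never alters them.
    """
    kept: list[formats.Read] = []
    discarded = 0
    fseq = fwd.iupac_sequence
    rseq = rev.reverse_complement()
    for read in reads:
        seq = read.sequence.upper()
        if (
            len(seq) < len(fseq) + len(rseq)
            or _mismatches(fseq, seq[: len(fseq)]) > max_mismatch
            or _mismatches(rseq, seq[-len(rseq):]) > max_mismatch
        ):
            discarded += 1
            continue
        insert = seq[len(fseq) : len(seq) - len(rseq)]
        quals = read.qualities[len(fseq) : len(seq) - len(rseq)] if read.qualities else None
        kept.append(formats.Read(read.read_id, insert, quals))
    return TrimResult(kept=kept, discarded=discarded)


# ---------------------------------------------------------------------------
# Published primer set


def load_primers(path: str | Path | None = None) -> dict[str, Primer]:
    """Load primers from a TSV (name, sequence, orientation).

    With no path, the package's bundled cutC/cntA primer set is used.
    """
    if path is None:
        with resources.as_file(
            resources.files("quatscreen.data") / "primers.tsv"
        ) as p:
            df = formats.read_primers_tsv(p)
    else:
        df = formats.read_primers_tsv(path)
    return {
        row["name"]: Primer(row["name"], row["sequence"], row["orientation"])
        for _, row in df.iterrows()
    }


def fetch_reference_cds(accessions: Sequence[str], out_dir: str | Path, email: str) -> None:
    """Fetch the coding sequences behind protein accessions from NCBI.

    Network-dependent convenience for completing the published product-size
    check (cutC/cntA amplicons of 275/249 bp on the coding sequences behind
    ACL49259 and EFK52065).  Writes one FASTA per accession into ``out_dir``.
    """
    from Bio import Entrez, SeqIO  # imported lazily: needs network to be useful

    Entrez.email = email
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for acc in accessions:
        with Entrez.efetch(db="protein", id=acc, rettype="gb", retmode="text") as h:
            rec = SeqIO.read(h, "genbank")
        coded_by = None
        for feat in rec.features:
            if feat.type == "CDS" and "coded_by" in feat.qualifiers:
                coded_by = feat.qualifiers["coded_by"][0]
        if coded_by is None:
            raise ValueError(f"{acc}: no coded_by qualifier")
        loc = coded_by.replace("complement(", "").rstrip(")")
        nuc_acc, span = loc.split(":")
        lo, hi = span.replace("<", "").replace(">", "").split("..")
        with Entrez.efetch(
            db="nuccore", id=nuc_acc, rettype="fasta", retmode="text",
            seq_start=int(lo), seq_stop=int(hi),
            strand=2 if coded_by.startswith("complement") else 1,
        ) as h:
            cds = SeqIO.read(h, "fasta")
        formats.write_fasta([(acc, str(cds.seq))], out_dir / f"{acc}.fna")
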