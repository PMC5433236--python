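"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the inputs the toolkit consumes in the field —
annotated genomes carrying planted pathway gene cassettes and decoy
homologs, amplicon read sets with controlled substitution/indel error,
shotgun metagenomes with known per-pathway carrier fractions, and
sample x cluster abundance matrices with planted rank-correlation blocks.
Every generator is a pure function of (spec, seed); the returned truth
records are sufficient to compute every expected downstream statistic
without re-running generation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable

from . import formats
from .formats import FeatureRecord, GenomeRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[11]
_CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in sorted(_CODON_TABLE.forward_table.items()):
    _CODONS_FOR.setdefault(aa, []).append(codon)


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def mutate_protein(
    rng: np.random.Generator,
    protein: str,
    divergence: float,
    protected: dict[int, str] | None = None,
) -> str:
    """Substitute residues at the given per-site rate; ``protected`` maps
    0-based positions to a residue forced at that site."""
    protected = protected or {}
    out = list(protein)
    for i in range(len(out)):
        if i in protected:
            out[i] = protected[i]
        elif rng.random() < divergence:
            choices = [a for a in AA20 if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def backtranslate(rng: np.random.Generator, protein: str, stop: bool = True) -> str:
    """Random back-translation, uniform over synonymous codons (table 11)."""
    codons = [ _CODONS_FOR[a][rng.integers(len(_CODONS_FOR[a]))] for a in protein ]
    if stop:
        stops = sorted(_CODON_TABLE.stop_codons)
        codons.append(stops[rng.integers(len(stops))])
    return "".join(codons)


@dataclass
class ProteinFamily:
    """A synthetic enzyme family: ancestor, seed alignment, signature sites."""

    name: str
    ancestor: str
    seeds: list[tuple[str, str]]
    signature_columns: dict[int, str] = field(default_factory=dict)  # 1-based

    @property
    def length(self) -> int:
        return len(self.ancestor)


def make_family(
    rng: np.random.Generator,
    length: int = 180,
    n_seeds: int = 8,
    divergence: float = 0.10,
    n_signatures: int = 3,
    name: str = "fam",
) -> ProteinFamily:
    ancestor = random_protein(rng, length)
    sig_pos = sorted(rng.choice(length, size=n_signatures, replace=False))
    signatures = {int(p) + 1: ancestor[p] for p in sig_pos}
    protected = {p: ancestor[p] for p in sig_pos}
    seeds = [
        (f"{name}_seed{i}", mutate_protein(rng, ancestor, divergence, protected))
        for i in range(n_seeds)
    ]
    return ProteinFamily(name=name, ancestor=ancestor, seeds=seeds, signature_columns=signatures)


# ---------------------------------------------------------------------------
# Genomes with planted cassettes


@dataclass
class GenomePlantSpec:
    n_genomes: int = 12
    separations: tuple[int, ...] = (1, 3, 5, 7, 10)  # syntenic target/partner pairs
    n_traps: int = 2            # targets with the partner just beyond the rule
    trap_separation: int = 11
    n_decoys: int = 50
    decoy_identity: tuple[float, float] = (0.50, 0.70)
    target_divergence: tuple[float, float] = (0.02, 0.12)
    backbone_genes: int = 24
    backbone_length: tuple[int, int] = (80, 200)
    target_length: int = 180
    partner_length: int = 140
    rplb_length: int = 90
    plant_rplb: bool = True


@dataclass
class PlantedGene:
    genome_id: str
    locus_tag: str
    locus_index: int
    kind: str  # target | partner | decoy | rplB
    identity_to_ancestor: float
    syntenic: bool | None = None
    separation: int | None = None


@dataclass
class GenomeTruth:
    seed: int
    planted: list[PlantedGene] = field(default_factory=list)
    target_family: ProteinFamily | None = None
    partner_family: ProteinFamily | None = None
    rplb_family: ProteinFamily | None = None

    def planted_of_kind(self, kind: str) -> list[PlantedGene]:
        return [p for p in self.planted if p.kind == kind]

    def to_json(self) -> dict:
        return {
            "seed": self.seed,
            "planted": [dataclasses.asdict(p) for p in self.planted],
        }


def _identity(a: str, b: str) -> float:
    return sum(1 for x, y in zip(a, b) if x == y) / max(len(a), len(b))


def make_genomes(
    spec: GenomePlantSpec, seed: int
) -> tuple[list[GenomeRecord], GenomeTruth]:
    """Genomes of random CDS backbones with planted target/partner cassettes,
    non-syntenous traps, and decoy homologs at controlled identity.

    Decoy cores are mutated to the requested identity band with every
    signature column scrambled to a disallowed residue.
    """
    rng = np.random.default_rng(seed)
    target_fam = make_family(rng, spec.target_length, name="target")
    partner_fam = make_family(rng, spec.partner_length, name="partner")
    rplb_fam = make_family(rng, spec.rplb_length, name="rplB", n_signatures=0)
    truth = GenomeTruth(seed=seed, target_family=target_fam,
                        partner_family=partner_fam, rplb_family=rplb_fam)

    # plan: genome g gets proteins[locus] inserted in a backbone
    plans: list[list[tuple[str, str, str]]] = [[] for _ in range(spec.n_genomes)]  # (kind, tag, protein)

    def _target_copy() -> tuple[str, float]:
        lo, hi = spec.target_divergence
        d = rng.uniform(lo, hi)
        prot = mutate_protein(
            rng, target_fam.ancestor, d,
            {p - 1: r for p, r in target_fam.signature_columns.items()},
        )
        return prot, _identity(prot, target_fam.ancestor)

    def _partner_copy() -> str:
        return mutate_protein(rng, partner_fam.ancestor, rng.uniform(0.02, 0.12))

    syntenic_specs = [(sep, True) for sep in spec.separations]
    syntenic_specs += [(spec.trap_separation, False)] * spec.n_traps
    for i, (sep, syn) in enumerate(syntenic_specs):
        g = i % spec.n_genomes
        tprot, ident = _target_copy()
        plans[g].append(("target", f"t{i}", tprot))
        plans[g].append(("partner", f"p{i}", _partner_copy()))
        truth.planted.append(
            PlantedGene(f"g{g:03d}", f"t{i}", -1, "target", ident, syntenic=syn, separation=sep)
        )
        truth.planted.append(
            PlantedGene(f"g{g:03d}", f"p{i}", -1, "partner", 1.0, syntenic=syn, separation=sep)
        )

    lo, hi = spec.decoy_identity
    scramble = {}
    for p, r in target_fam.signature_columns.items():
        alt = [a for a in AA20 if a != r]
        scramble[p - 1] = alt[rng.integers(len(alt))]
    for i in range(spec.n_decoys):
        g = int(rng.integers(spec.n_genomes))
        d = 1.0 - rng.uniform(lo, hi)
        prot = mutate_protein(rng, target_fam.ancestor, d, scramble)
        plans[g].append(("decoy", f"d{i}", prot))
        truth.planted.append(
            PlantedGene(f"g{g:03d}", f"d{i}", -1, "decoy", _identity(prot, target_fam.ancestor))
        )

    genomes: list[GenomeRecord] = []
    pair_info = {
        f"t{i}": (sep, syn) for i, (sep, syn) in enumerate(syntenic_specs)
    }
    for g in range(spec.n_genomes):
        gid = f"g{g:03d}"
        backbone = [
            ("backbone", f"b{j}", random_protein(rng, int(rng.integers(*spec.backbone_length))))
            for j in range(spec.backbone_genes)
        ]
        if spec.plant_rplb:
            backbone.append(("rplB", "rplB", mutate_protein(rng, rplb_fam.ancestor, rng.uniform(0.02, 0.10))))
            truth.planted.append(PlantedGene(gid, "rplB", -1, "rplB", 1.0))
        rng.shuffle(backbone)
        genes: list[tuple[str, str, str]] = list(backbone)
        # insert decoys at random positions
        for kind, tag, prot in plans[g]:
            if kind == "decoy":
                pos = int(rng.integers(len(genes) + 1))
                genes.insert(pos, (kind, tag, prot))
        # insert target/partner pairs at controlled separation
        for kind, tag, prot in plans[g]:
            if kind != "target":
                continue
            sep, _syn = pair_info[tag]
            partner_entry = next(e for e in plans[g] if e[0] == "partner" and e[1] == "p" + tag[1:])
            pos = int(rng.integers(max(1, len(genes) - sep)))
            genes.insert(pos, (kind, tag, prot))
            genes.insert(pos + sep, partner_entry)
        # lay out on one contig
        features = []
        cursor = 1
        contig_parts = []
        for idx, (kind, tag, prot) in enumerate(genes):
            nt = backtranslate(rng, prot)
            strand = "+" if rng.random() < 0.5 else "-"
            placed = nt if strand == "+" else formats.reverse_complement(nt)
            start = cursor
            end = cursor + len(nt) - 1
            features.append(
                FeatureRecord(
                    genome_id=gid, contig_id="c1", start=start, end=end,
                    strand=strand, locus_tag=tag if kind != "backbone" else f"{tag}_{idx}",
                    protein=prot, gene_nt=nt, locus_index=idx,
                )
            )
            contig_parts.append(placed)
            spacer = "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 80))))
            contig_parts.append(spacer)
            cursor = end + len(spacer) + 1
        contig = "".join(contig_parts)
        for p in truth.planted:
            if p.genome_id == gid:
                for f in features:
                    if f.locus_tag == p.locus_tag:
                        p.locus_index = f.locus_index
        genomes.append(GenomeRecord(genome_id=gid, contigs={"c1": contig}, features=features))
    return genomes, truth


# ---------------------------------------------------------------------------
# Amplicon reads


@dataclass
class AmpliconTruth:
    seed: int
    proportions: dict[str, float]
    reads: dict[str, dict] = field(default_factory=dict)  # read_id -> events

    def empirical_proportions(self) -> dict[str, float]:
        counts: dict[str, int] = {}
        for info in self.reads.values():
            counts[info["source"]] = counts.get(info["source"], 0) + 1
        total = sum(counts.values())
        return {k: v / total for k, v in counts.items()}

    def retained_proportions(self) -> dict[str, float]:
        """Composition of the reads a stop-codon filter is expected to keep."""
        counts: dict[str, int] = {}
        for info in self.reads.values():
            if not info.get("stop_in_frame"):
                counts[info["source"]] = counts.get(info["source"], 0) + 1
        total = sum(counts.values())
        return {k: v / total for k, v in counts.items()}


def make_amplicons(
    refs: dict[str, str],
    proportions: dict[str, float],
    n_reads: int,
    sub_rate: float = 0.01,
    indel_rate: float = 0.005,
    seed: int = 0,
    sample_id: str = "s1",
    quality: int = 37,
) -> tuple[list[formats.Read], AmpliconTruth]:
    """Reads drawn from reference amplicon regions with planted errors.

    Substitutions occur per base at ``sub_rate``; insertions and deletions
    each at ``indel_rate/2``, so truth records make every read's expected
    frameshift count checkable.  Qualities are constant.
    """
    rng = np.random.default_rng(seed)
    ids = sorted(refs)
    p = np.array([proportions[i] for i in ids], dtype=float)
    p = p / p.sum()
    truth = AmpliconTruth(seed=seed, proportions={i: float(x) for i, x in zip(ids, p)})
    reads = []
    for n in range(n_reads):
        src = ids[rng.choice(len(ids), p=p)]
        seq = refs[src]
        out = []
        repaired = []  # frame-restored view: insertions dropped, deletions padded
        ins_pos: list[int] = []
        del_pos: list[int] = []
        n_sub = 0
        for pos, base in enumerate(seq):
            r = rng.random()
            if r < indel_rate / 2:
                del_pos.append(pos)
                repaired.append(base)  # a frame repair pads toward the reference
                continue
            if r < indel_rate:
                out.append("ACGT"[rng.integers(4)])
                ins_pos.append(pos)
            if rng.random() < sub_rate:
                alt = [b for b in "ACGT" if b != base]
                out.append(alt[rng.integers(3)])
                n_sub += 1
            else:
                out.append(base)
            repaired.append(out[-1])
        rid = f"{sample_id}_r{n:06d}"
        reads.append(formats.Read(rid, "".join(out), [quality] * len(out)))
        truth.reads[rid] = {
            "source": src,
            "n_sub": n_sub,
            "n_ins": len(ins_pos),
            "n_del": len(del_pos),
            "ins_positions": ins_pos,
            "del_positions": del_pos,
            "stop_in_frame": "*" in formats.translate("".join(repaired)),
        }
    return reads, truth


def split_pairs(
    reads: list[formats.Read], read_len: int
) -> tuple[list[formats.Read], list[formats.Read]]:
    """Emulate paired-end sequencing of merged fragments: R1 is the first
    ``read_len`` bases, R2 the reverse complement of the last ``read_len``."""
    r1, r2 = [], []
    for r in reads:
        q = r.qualities or [37] * len(r.sequence)
        r1.append(formats.Read(r.read_id, r.sequence[:read_len], q[:read_len]))
        r2.append(
            formats.Read(
                r.read_id,
                formats.reverse_complement(r.sequence[-read_len:]),
                list(reversed(q[-read_len:])),
            )
        )
    return r1, r2


# ---------------------------------------------------------------------------
# Metagenomes


@dataclass
class MetagenomeTruth:
    seed: int
    carrier_fraction: dict[str, float]  # pathway -> f
    expected_percent: dict[str, float]
    n_reads: int


def make_metagenome(
    genomes: list[GenomeRecord],
    carriers: dict[str, set[str]],
    depth: float = 20.0,
    read_len: int = 150,
    seed: int = 0,
    quality: int = 37,
) -> tuple[list[formats.Read], MetagenomeTruth]:
    """Uniform shotgun fragmentation of an equal-abundance community.

    ``carriers`` maps pathway name -> set of genome_ids that carry it
    (single copy); the analytic expectation recorded in the truth is
    100 x carrier fraction.
    """
    rng = np.random.default_rng(seed)
    lens = np.array([len(g.contigs["c1"]) for g in genomes], dtype=float)
    total = lens.sum()
    n_reads = int(round(depth * total / read_len))
    weights = lens / total
    reads = []
    for n in range(n_reads):
        gi = rng.choice(len(genomes), p=weights)
        contig = genomes[gi].contigs["c1"]
        if len(contig) <= read_len:
            frag = contig
        else:
            start = int(rng.integers(len(contig) - read_len + 1))
            frag = contig[start : start + read_len]
        if rng.random() < 0.5:
            frag = formats.reverse_complement(frag)
        reads.append(formats.Read(f"m{n:07d}", frag, [quality] * len(frag)))
    frac = {p: len(c) / len(genomes) for p, c in carriers.items()}
    truth = MetagenomeTruth(
        seed=seed,
        carrier_fraction=frac,
        expected_percent={p: 100.0 * f for p, f in frac.items()},
        n_reads=n_reads,
    )
    return reads, truth


# ---------------------------------------------------------------------------
# Abundance matrices with planted correlation blocks


@dataclass
class MatrixTruth:
    seed: int
    correlated_pairs: list[tuple[str, str]]
    prevalence: dict[str, float]


def make_abundance_matrix(
    n_samples: int = 50,
    n_clusters: int = 20,
    blocks: list[list[int]] | None = None,
    low_prevalence: dict[int, float] | None = None,
    seed: int = 0,
    depth: int = 2000,
) -> tuple["pd.DataFrame", MatrixTruth]:
    """Log-normal sample x cluster counts with planted rho=1 rank blocks.

    Clusters inside a block share a monotone transform of one latent series
    (Spearman rho exactly 1 on the underlying abundances); all other
    clusters are independent.  ``low_prevalence`` maps cluster index ->
    presence fraction, zeroing the cluster elsewhere.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    blocks = blocks or []
    low_prevalence = low_prevalence or {}
    in_block = {c for b in blocks for c in b}
    names = [f"cl{j:03d}" for j in range(n_clusters)]
    mat = np.zeros((n_samples, n_clusters))
    for b in blocks:
        latent = rng.normal(size=n_samples)
        for c in b:
            a = rng.uniform(0.5, 2.0)
            mat[:, c] = np.exp(1.0 + a * latent)
    for j in range(n_clusters):
        if j not in in_block:
            mat[:, j] = np.exp(rng.normal(1.0, 1.0, size=n_samples))
    for j, frac in low_prevalence.items():
        present = rng.random(n_samples) < frac
        mat[~present, j] = 0.0
    rel = mat / mat.sum(axis=1, keepdims=True)
    counts = np.floor(rel * depth).astype(int)
    df = pd.DataFrame(counts, index=[f"s{i:03d}" for i in range(n_samples)], columns=names)
    pairs = []
    for b in blocks:
        for i, c1 in enumerate(b):
            for c2 in b[i + 1 :]:
                pairs.append((names[c1], names[c2]))
    prevalence = {names[j]: float((df[names[j]] > 0).mean()) for j in range(n_clusters)}
    return df, MatrixTruth(seed=seed, correlated_pairs=pairs, prevalence=prevalence)


# ---------------------------------------------------------------------------
# Serialization


def write_truth(truth, path: str | Path) -> None:
    obj = truth.to_json() if hasattr(truth, "to_json") else dataclasses.asdict(truth)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=str)
        fh.write("\n")


def write_genomes(genomes: list[GenomeRecord], out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for g in genomes:
        formats.write_fasta(sorted(g.contigs.items()), out_dir / f"{g.genome_id}.fna")
        formats.write_features_tsv(g.features, out_dir / f"{g.genome_id}.features.tsv")
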