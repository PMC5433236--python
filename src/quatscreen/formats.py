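"""Readers and writers for on-disk artifacts.

Everything that touches a file format lives here so that the computational
modules only ever see in-memory records.  Coordinates are 1-based inclusive
on disk (GFF convention) and 0-based half-open in memory.  The bacterial
genetic code (NCBI table 11) is the default throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

DEFAULT_GENETIC_CODE = 11

#: Columns of the package's tab-separated feature dialect.
FEATURE_TSV_COLUMNS = [
    "genome_id",
    "contig_id",
    "start",
    "end",
    "strand",
    "locus_tag",
    "protein",
]

HIT_TABLE_COLUMNS = [
    "query_id",
    "ref_id",
    "identity",
    "aligned_length",
    "mismatches",
    "gap_openings",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "evalue",
    "bitscore",
]


class FormatError(ValueError):
    """Raised when an on-disk artifact does not parse."""


@dataclass
class FeatureRecord:
    """One protein-coding feature of a genome.

    ``locus_index`` is the 0-based position of the feature among all features
    on its contig in coordinate order; gene-neighbourhood ("synteny") rules
    count locus-index differences.  ``start``/``end`` are kept 1-based
    inclusive to match the on-disk convention.
    """

    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    locus_tag: str
    protein: str = ""
    gene_nt: str = ""
    locus_index: int = -1

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"feature {self.locus_tag}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise FormatError(f"feature {self.locus_tag}: bad strand {self.strand!r}")


@dataclass
class GenomeRecord:
    """Contigs plus coordinate-ordered features of one genome."""

    genome_id: str
    contigs: dict[str, str]
    features: list[FeatureRecord] = field(default_factory=list)

    def features_on(self, contig_id: str) -> list[FeatureRecord]:
        return [f for f in self.features if f.contig_id == contig_id]

    def proteins(self) -> list[tuple[FeatureRecord, str]]:
        return [(f, f.protein) for f in self.features if f.protein]


def translate(nt: str, table: int = DEFAULT_GENETIC_CODE) -> str:
    """Translate an in-frame nucleotide string (frame 0, given code table)."""
    n = len(nt) - len(nt) % 3
    return str(Seq(nt[:n]).translate(table=table))


def reverse_complement(nt: str) -> str:
    return str(Seq(nt).reverse_complement())


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _attach_gene_nt(feature: FeatureRecord, contigs: dict[str, str]) -> None:
    seq = contigs[feature.contig_id][feature.start - 1 : feature.end]
    feature.gene_nt = seq if feature.strand == "+" else reverse_complement(seq)


def _assign_locus_indices(features: list[FeatureRecord]) -> None:
    by_contig: dict[str, list[FeatureRecord]] = {}
    for f in features:
        by_contig.setdefault(f.contig_id, []).append(f)
    for group in by_contig.values():
        group.sort(key=lambda f: (f.start, f.end, f.locus_tag))
        for i, f in enumerate(group):
            f.locus_index = i


def _read_features_tsv(path: Path, genome_id: str) -> list[FeatureRecord]:
    features: list[FeatureRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        cols = header.split("\t")
        if cols != FEATURE_TSV_COLUMNS:
            raise FormatError(
                f"{path}: expected feature columns {FEATURE_TSV_COLUMNS}, got {cols}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(FEATURE_TSV_COLUMNS):
                raise FormatError(f"{path}:{lineno}: expected {len(FEATURE_TSV_COLUMNS)} fields")
            try:
                start, end = int(parts[2]), int(parts[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            features.append(
                FeatureRecord(
                    genome_id=parts[0] or genome_id,
                    contig_id=parts[1],
                    start=start,
                    end=end,
                    strand=parts[4],
                    locus_tag=parts[5],
                    protein=parts[6],
                )
            )
    return features


def _read_features_gff3(path: Path, genome_id: str) -> list[FeatureRecord]:
    features: list[FeatureRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            if parts[2] != "CDS":
                continue
            attrs = {}
            for item in parts[8].split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attrs[k.strip()] = v.strip()
            features.append(
                FeatureRecord(
                    genome_id=genome_id,
                    contig_id=parts[0],
                    start=int(parts[3]),
                    end=int(parts[4]),
                    strand=parts[6],
                    locus_tag=attrs.get("locus_tag", attrs.get("ID", f"cds{lineno}")),
                    protein=attrs.get("translation", ""),
                )
            )
    return features


def read_genome(
    fasta_path: str | Path,
    features_path: str | Path,
    genome_id: str | None = None,
    genetic_code: int = DEFAULT_GENETIC_CODE,
) -> GenomeRecord:
    """Load a genome from a contig FASTA plus a feature table (TSV or GFF3).

    Features referring to a contig absent from the FASTA are a hard error.
    Locus indices are assigned per contig by sorted start coordinate.  When a
    feature carries no protein translation but spans an in-frame CDS, the
    translation is derived from the contig.
    """
    fasta_path, features_path = Path(fasta_path), Path(features_path)
    contigs = read_fasta(fasta_path)
    gid = genome_id or fasta_path.stem
    if features_path.suffix.lower() in {".gff", ".gff3"}:
        features = _read_features_gff3(features_path, gid)
    else:
        features = _read_features_tsv(features_path, gid)
    for f in features:
        if f.contig_id not in contigs:
            raise FormatError(
                f"feature {f.locus_tag} refers to contig {f.contig_id!r} "
                f"absent from {fasta_path.name}"
            )
        _attach_gene_nt(f, contigs)
        if not f.protein and f.gene_nt:
            f.protein = translate(f.gene_nt, genetic_code).rstrip("*")
    _assign_locus_indices(features)
    return GenomeRecord(genome_id=gid, contigs=contigs, features=features)


def write_features_tsv(features: Sequence[FeatureRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(FEATURE_TSV_COLUMNS) + "\n")
        for f in features:
            fh.write(
                "\t".join(
                    [f.genome_id, f.contig_id, str(f.start), str(f.end), f.strand, f.locus_tag, f.protein]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Candidate table round-trip


def write_candidate_table(table: pd.DataFrame, path: str | Path, precision: int = 4) -> None:
    """Write a candidate table as TSV with header at fixed float precision."""
    table.to_csv(path, sep="\t", index=False, float_format=f"%.{precision}f")


def read_candidate_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "score" in df.columns and not pd.api.types.is_numeric_dtype(df["score"]):
        bad = df.index[pd.to_numeric(df["score"], errors="coerce").isna()]
        line = int(bad[0]) + 2 if len(bad) else "?"
        raise FormatError(f"{path}:{line}: non-numeric score field")
    return df


def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Read search hits in BLAST tabular (outfmt 6) compatible columns."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=HIT_TABLE_COLUMNS, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=HIT_TABLE_COLUMNS)
    for lineno, val in enumerate(df["bitscore"], start=1):
        try:
            float(val)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric bitscore {val!r}") from exc
    df["identity"] = df["identity"].astype(float)
    return df


# ---------------------------------------------------------------------------
# FASTQ helpers


@dataclass
class Read:
    read_id: str
    sequence: str
    qualities: list[int] | None = None


def read_fastq(path: str | Path) -> list[Read]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(Read(rec.id, str(rec.seq).upper(), rec.letter_annotations["phred_quality"]))
    return reads


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            quals = r.qualities or [37] * len(r.sequence)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n")
            fh.write("".join(chr(q + 33) for q in quals) + "\n")


def read_sequences(path: str | Path) -> list[Read]:
    """Read FASTA or FASTQ based on the leading character."""
    with open(path) as fh:
        first = fh.read(1)
    if first == "@":
        return read_fastq(path)
    return [Read(name, seq) for name, seq in read_fasta(path).items()]


# ---------------------------------------------------------------------------
# Primer TSV


def read_primers_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"name", "sequence", "orientation"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: primer TSV needs columns {sorted(required)}")
    return df


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
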