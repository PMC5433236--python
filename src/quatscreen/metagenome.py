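"""Screening shotgun reads for TMA-pathway gene pairs and quantifying them.

Reads are quality-filtered, searched against a nucleotide reference set
(targets plus top-scoring below-threshold outgroup sequences, so near-miss
homologs are captured and rejected), filtered at >=70 aligned bp and >=70%
identity on the read's top hit, and counted per gene.  Pathway abundance is
the median of the two genes' length-normalized counts relative to the
length-normalized count of the universal single-copy gene rplB, reported as
a percentage of the community; a pathway requires both of its genes to be
detected.  Retained reads inherit the taxonomic bin (90% reference cluster
or genus) of their top-hit reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from . import formats
from .dbbuild import GeneDatabase, screen_genomes
from .formats import GenomeRecord
from .profile import ProfileModel

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Read QC


def qc_reads(
    reads: list[formats.Read], min_q: int = 30, min_frac: float = 0.5
) -> list[formats.Read]:
    """Keep reads where at least ``min_frac`` of bases reach quality ``min_q``.

    Reads without qualities (FASTA input) pass through unchanged.
    """
    out = []
    for r in reads:
        if not r.qualities:
            out.append(r)
            continue
        q = np.asarray(r.qualities)
        if len(q) and (q >= min_q).mean() >= min_frac:
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# Similarity search (pluggable: internal engine or BLAST tabular input)


@dataclass
class SearchHit:
    read_id: str
    ref_id: str
    aligned_length: int
    identity: float
    evalue: float
    bitscore: float


class KmerIndex:
    """Exact k-mer prefilter: maps k-mers of the references to ref ids."""

    def __init__(self, refs: dict[str, str], k: int = 12):
        self.k = k
        self.refs = refs
        self.index: dict[str, set[str]] = {}
        for rid, seq in refs.items():
            s = seq.upper()
            for i in range(0, len(s) - k + 1):
                self.index.setdefault(s[i : i + k], set()).add(rid)

    def candidates(self, read: str) -> set[str]:
        k = self.k
        cands: set[str] = set()
        s = read.upper()
        for i in range(0, len(s) - k + 1, k):  # non-overlapping stride is enough
            cands |= self.index.get(s[i : i + k], set())
        return cands


def _align_stats(query: str, target: str) -> tuple[int, int, int] | None:
    """(matches, alignment_columns, read_consumed_bp) of the best infix
    alignment of query in target, or None if nothing aligns."""
    res = edlib.align(query, target, mode="HW", task="path")
    if res["editDistance"] < 0:
        return None
    cols = eq = readbp = 0
    num = ""
    for ch in res["cigar"] or "":
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        cols += n
        if ch == "=":
            eq += n
            readbp += n
        elif ch == "X":
            readbp += n
        elif ch == "I":  # insertion relative to target: consumes query
            readbp += n
    return eq, cols, readbp


def search_reads(
    reads: list[formats.Read],
    refset: dict[str, str],
    min_len: int = 70,
    min_id: float = 0.70,
    engine: str = "blast",
) -> list[SearchHit]:
    """Top-hit nucleotide search of reads against a reference set.

    Each read keeps only its best hit, filtered at ``min_len`` aligned bp
    and ``min_id`` identity.  The default engine shells out to blastn
    (local alignment, so reads partially overlapping a gene are scored on
    the overlapping region, as the 70 bp rule requires); the ``internal``
    engine is a k-mer seeded infix aligner that requires reads to lie
    essentially within a reference.
    """
    if not refset:
        raise ValueError("empty reference set")
    if engine == "blast":
        return _search_reads_blast(reads, refset, min_len, min_id)
    if engine == "internal":
        return _search_reads_internal(reads, refset, min_len, min_id)
    raise ValueError(f"unknown search engine {engine!r}")


def _search_reads_blast(
    reads: list[formats.Read],
    refset: dict[str, str],
    min_len: int,
    min_id: float,
) -> list[SearchHit]:
    import subprocess
    import tempfile
    from pathlib import Path

    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        formats.write_fasta(sorted(refset.items()), tmp / "refs.fna")
        formats.write_fasta(((r.read_id, r.sequence) for r in reads), tmp / "reads.fna")
        subprocess.run(
            ["makeblastdb", "-in", str(tmp / "refs.fna"), "-dbtype", "nucl",
             "-out", str(tmp / "refdb")],
            check=True, capture_output=True,
        )
        subprocess.run(
            ["blastn", "-task", "blastn", "-query", str(tmp / "reads.fna"),
             "-db", str(tmp / "refdb"), "-outfmt", "6",
             "-max_target_seqs", "20", "-num_threads", "1",
             "-out", str(tmp / "hits.tsv")],
            check=True, capture_output=True,
        )
        df = formats.read_hit_table(tmp / "hits.tsv")
    return hits_from_table(df, min_len=min_len, min_id=min_id)


def _search_reads_internal(
    reads: list[formats.Read],
    refset: dict[str, str],
    min_len: int = 70,
    min_id: float = 0.70,
    k: int = 12,
) -> list[SearchHit]:
    index = KmerIndex(refset, k=k)
    hits: list[SearchHit] = []
    for read in reads:
        seq = read.sequence.upper()
        rc = formats.reverse_complement(seq)
        cands = index.candidates(seq) | index.candidates(rc)
        best = None
        for rid in sorted(cands):
            ref = refset[rid]
            for q in (seq, rc):
                stats = _align_stats(q, ref)
                if stats is None:
                    continue
                eq, cols, readbp = stats
                identity = eq / cols if cols else 0.0
                # blast-like score: +2 match, -3 mismatch/gap column
                score = 2.0 * eq - 3.0 * (cols - eq)
                key = (-score, -identity, rid)
                if best is None or key < best[0]:
                    best = (key, SearchHit(read.read_id, rid, readbp, identity, float("nan"), score))
        if best is None:
            continue
        hit = best[1]
        if hit.aligned_length >= min_len and hit.identity >= min_id:
            hits.append(hit)
    return hits


def hits_from_table(
    df: pd.DataFrame, min_len: int = 70, min_id: float = 0.70
) -> list[SearchHit]:
    """Top-hit selection and filtering from BLAST tabular (outfmt 6) hits.

    Top hit per read by e-value; ties by higher bitscore then lexicographic
    reference id.  Identity is accepted on the 0-100 scale and converted.
    """
    hits: list[SearchHit] = []
    if df.empty:
        return hits
    df = df.copy()
    if df["identity"].max() > 1.5:
        df["identity"] = df["identity"] / 100.0
    df = df.sort_values(
        ["query_id", "evalue", "bitscore", "ref_id"], ascending=[True, True, False, True]
    )
    top = df.groupby("query_id", sort=False).head(1)
    for _, row in top.iterrows():
        if row["aligned_length"] >= min_len and row["identity"] >= min_id:
            hits.append(
                SearchHit(
                    read_id=str(row["query_id"]),
                    ref_id=str(row["ref_id"]),
                    aligned_length=int(row["aligned_length"]),
                    identity=float(row["identity"]),
                    evalue=float(row["evalue"]),
                    bitscore=float(row["bitscore"]),
                )
            )
    return hits


def split_hits(
    hits: list[SearchHit], target_ids: set[str]
) -> tuple[list[SearchHit], list[SearchHit]]:
    """Partition hits into (target, outgroup); outgroup hits are recorded
    but excluded from abundance."""
    target = [h for h in hits if h.ref_id in target_ids]
    outgroup = [h for h in hits if h.ref_id not in target_ids]
    return target, outgroup


# ---------------------------------------------------------------------------
# Pathway abundance


@dataclass
class PathwayAbundance:
    sample_id: str
    pathway: str
    gene_counts: dict[str, int]
    gene_abundance: dict[str, float]  # length-normalized
    rplb_abundance: float
    percent_of_community: float
    detected: bool


def pathway_abundance(
    hits_by_gene: dict[str, list[SearchHit]],
    hits_rplb: list[SearchHit],
    ref_lengths: dict[str, float],
    sample_id: str = "sample",
    pathway: str = "pathway",
) -> PathwayAbundance:
    """Median-of-genes abundance relative to gene-length-corrected rplB.

    Per gene g, a_g = retained read count / median reference length (bp);
    likewise for rplB; percent = 100 * median(a_g) / a_rplB.  If any gene of
    the pathway has no retained read, or rplB is absent, the pathway is
    reported as not detected (percent 0).
    """
    counts = {g: len(h) for g, h in hits_by_gene.items()}
    abundance = {
        g: counts[g] / ref_lengths[g] if ref_lengths.get(g) else 0.0 for g in hits_by_gene
    }
    rplb_count = len(hits_rplb)
    rplb_abund = rplb_count / ref_lengths["rplB"] if ref_lengths.get("rplB") else 0.0
    detected = all(c > 0 for c in counts.values()) and rplb_count > 0 and len(counts) > 0
    percent = (
        100.0 * float(np.median(list(abundance.values()))) / rplb_abund if detected else 0.0
    )
    return PathwayAbundance(
        sample_id=sample_id,
        pathway=pathway,
        gene_counts=counts,
        gene_abundance=abundance,
        rplb_abundance=rplb_abund,
        percent_of_community=percent,
        detected=detected,
    )


def taxon_profile(
    hits_by_gene: dict[str, list[SearchHit]],
    reference_bins: dict[str, str],
    ref_lengths: dict[str, float],
) -> pd.DataFrame:
    """Per-taxon pathway abundance from top-hit reference bins.

    Each retained read inherits the bin (90% reference cluster or genus) of
    its top-hit reference; per taxon the median across the pathway's genes
    of the length-normalized binned counts is reported, ranked descending.
    """
    genes = sorted(hits_by_gene)
    taxa = sorted({reference_bins.get(h.ref_id, "unbinned") for hs in hits_by_gene.values() for h in hs})
    rows = []
    for taxon in taxa:
        per_gene = []
        for g in genes:
            n = sum(1 for h in hits_by_gene[g] if reference_bins.get(h.ref_id, "unbinned") == taxon)
            per_gene.append(n / ref_lengths[g] if ref_lengths.get(g) else 0.0)
        rows.append({"taxon": taxon, "abundance": float(np.median(per_gene)),
                     **{f"count_{g}": sum(1 for h in hits_by_gene[g] if reference_bins.get(h.ref_id, "unbinned") == taxon) for g in genes}})
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values("abundance", ascending=False, kind="stable").reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# rplB reference building


@dataclass
class RplbRefset:
    refs: dict[str, str]  # ref_id -> nt
    median_length: float
    missing_genomes: list[str] = field(default_factory=list)


def rplb_reference_builder(
    genomes: list[GenomeRecord],
    rplb_model: ProfileModel,
    min_score_fraction: float = 0.5,
) -> RplbRefset:
    """Extract the best-scoring rplB gene of every genome.

    A feature qualifies when it scores at least ``min_score_fraction`` of
    the top rplB score across all genomes (a universal single-copy gene is
    expected in every genome at a similar score).  Genomes without a
    qualifying feature are listed with a warning.
    """
    hits = screen_genomes(genomes, rplb_model, top_n=None)
    threshold = min_score_fraction * hits[0].score if hits else 0.0
    best: dict[str, "object"] = {}
    for h in hits:
        if h.score >= threshold and h.genome_id not in best:
            best[h.genome_id] = h
    missing = sorted({g.genome_id for g in genomes} - set(best))
    if missing:
        log.warning("no rplB found in genomes: %s", ", ".join(missing))
    refs = {
        f"{gid}.{h.feature.locus_tag}": h.gene_nt for gid, h in sorted(best.items())
    }
    median_len = float(np.median([len(s) for s in refs.values()])) if refs else 0.0
    return RplbRefset(refs=refs, median_length=median_len, missing_genomes=missing)


# ---------------------------------------------------------------------------
# Orchestration


@dataclass
class QuantifyResult:
    abundance: PathwayAbundance
    taxa: pd.DataFrame
    n_reads_in: int
    n_reads_qc: int
    outgroup_hits: dict[str, int]


def quantify_pathway(
    reads: list[formats.Read],
    gene_dbs: dict[str, GeneDatabase],
    rplb: RplbRefset,
    sample_id: str = "sample",
    pathway: str | None = None,
    min_q: int = 30,
    min_frac: float = 0.5,
    min_len: int = 70,
    min_id: float = 0.70,
    engine: str = "blast",
) -> QuantifyResult:
    """QC reads, search each gene's reference set and rplB, and quantify."""
    n_in = len(reads)
    reads = qc_reads(reads, min_q=min_q, min_frac=min_frac)
    hits_by_gene: dict[str, list[SearchHit]] = {}
    outgroup_tally: dict[str, int] = {}
    ref_lengths: dict[str, float] = {}
    bins: dict[str, str] = {}
    for gene, db in gene_dbs.items():
        refset = dict(db.target_nt())
        target_ids = set(refset)
        for r in db.outgroup_nt_refs:
            refset[f"og:{r.ref_id}"] = r.nt
        hits = search_reads(reads, refset, min_len=min_len, min_id=min_id, engine=engine)
        target_hits, og_hits = split_hits(hits, target_ids)
        hits_by_gene[gene] = target_hits
        outgroup_tally[gene] = len(og_hits)
        ref_lengths[gene] = float(np.median([len(s) for s in db.target_nt().values()])) if db.target_refs else 0.0
        for r in db.target_refs:
            bins[r.ref_id] = r.cluster90 or r.taxonomy or "unbinned"
    rplb_hits = (
        search_reads(reads, rplb.refs, min_len=min_len, min_id=min_id, engine=engine)
        if rplb.refs
        else []
    )
    ref_lengths["rplB"] = rplb.median_length
    abundance = pathway_abundance(
        hits_by_gene, rplb_hits, ref_lengths, sample_id=sample_id,
        pathway=pathway or "/".join(sorted(gene_dbs)),
    )
    taxa = taxon_profile(hits_by_gene, bins, ref_lengths)
    return QuantifyResult(
        abundance=abundance,
        taxa=taxa,
        n_reads_in=n_in,
        n_reads_qc=len(reads),
        outgroup_hits=outgroup_tally,
    )
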