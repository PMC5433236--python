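"""From raw functional-gene amplicon reads to community-level summaries.

Stages: paired-read merging and quality filtering, frameshift correction
against target + outgroup protein references, target discrimination (reject
non-target homologs and stop-codon pseudogenes), codon-aware clustering at
nucleotide identity cutoffs with complete linkage, rarefaction, diversity
and prevalence summaries, best-match identity to references, Spearman/FDR
co-occurrence networks and Bray-Curtis NMDS ordination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr
from sklearn.manifold import MDS
from statsmodels.stats.multitest import multipletests

import edlib

from . import cluster as _cluster
from . import formats, frameshift
from .frameshift import FrameshiftParams
from .profile import ProfileModel

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Merging


@dataclass
class MergeStats:
    pairs_in: int = 0
    merged: int = 0
    no_overlap: int = 0
    low_quality: int = 0


def merge_pair(
    r1: formats.Read,
    r2: formats.Read,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
) -> formats.Read | None:
    """Merge a read pair by the best ungapped 3' overlap.

    The reverse read is reverse-complemented, every overlap length from the
    longest down is scored, and the first (longest) overlap with a mismatch
    fraction <= ``max_mismatch_frac`` wins; in the overlap the base with the
    higher quality is called and its quality kept.
    """
    s1, q1 = r1.sequence, r1.qualities or [30] * len(r1.sequence)
    s2 = formats.reverse_complement(r2.sequence)
    q2 = list(reversed(r2.qualities or [30] * len(r2.sequence)))
    best = None
    for olap in range(min(len(s1), len(s2)), min_overlap - 1, -1):
        a = s1[-olap:]
        b = s2[:olap]
        mism = sum(1 for x, y in zip(a, b) if x != y)
        if mism / olap <= max_mismatch_frac:
            best = olap
            break
    if best is None:
        return None
    olap = best
    head = s1[:-olap]
    qhead = q1[: len(head)]
    mid = []
    qmid = []
    for i in range(olap):
        ia = len(s1) - olap + i
        if q1[ia] >= q2[i]:
            mid.append(s1[ia])
            qmid.append(q1[ia])
        else:
            mid.append(s2[i])
            qmid.append(q2[i])
    tail = s2[olap:]
    qtail = q2[olap:]
    return formats.Read(r1.read_id, head + "".join(mid) + tail, qhead + qmid + qtail)


def merge_and_filter(
    reads1: list[formats.Read],
    reads2: list[formats.Read],
    min_q: float = 25.0,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
) -> tuple[list[formats.Read], MergeStats]:
    """Merge paired reads and drop merged reads below mean quality ``min_q``."""
    by_id = {r.read_id: r for r in reads2}
    missing = [r.read_id for r in reads1 if r.read_id not in by_id]
    if missing or len(reads1) != len(reads2):
        offender = missing[0] if missing else "<count mismatch>"
        raise ValueError(f"unpaired read ids (first offender: {offender})")
    stats = MergeStats(pairs_in=len(reads1))
    out = []
    for r1 in reads1:
        merged = merge_pair(r1, by_id[r1.read_id], min_overlap, max_mismatch_frac)
        if merged is None:
            stats.no_overlap += 1
            continue
        if merged.qualities and float(np.mean(merged.qualities)) < min_q:
            stats.low_quality += 1
            continue
        stats.merged += 1
        out.append(merged)
    return out, stats


# ---------------------------------------------------------------------------
# Frameshift correction against a reference panel


@dataclass
class CorrectedAmplicon:
    read_id: str
    sample_id: str
    corrected_nt: str
    corrected_protein: str
    closest_ref_id: str
    protein_identity: float
    frameshift_count: int
    has_stop: bool
    is_target: bool
    score: float = 0.0
    ref_positions: list[int] = field(default_factory=list)
    """Per corrected codon: the 0-based residue of the closest reference it
    is aligned to (-1 for codons inserted relative to the reference)."""


def frameshift_correct(
    read_nt: str,
    reference_proteins: dict[str, str],
    target_ids: set[str],
    read_id: str = "read",
    sample_id: str = "sample",
    params: FrameshiftParams | None = None,
) -> CorrectedAmplicon:
    """Correct one read against every reference; the best score wins.

    Ties go to the higher protein identity, then the lexicographically
    smallest reference id.  ``is_target`` requires the winning reference to
    be a target and the corrected frame to be stop-free.
    """
    if len(read_nt) < 3:
        raise ValueError("read shorter than one codon")
    params = params or FrameshiftParams()
    best = None
    best_key = None
    for rid in sorted(reference_proteins):
        res = frameshift.correct_read(read_nt, reference_proteins[rid], params)
        key = (-res.score, -res.identity, rid)
        if best_key is None or key < best_key:
            best_key = key
            best = (rid, res)
    rid, res = best
    return CorrectedAmplicon(
        read_id=read_id,
        sample_id=sample_id,
        corrected_nt=res.corrected_nt,
        corrected_protein=res.corrected_protein,
        closest_ref_id=rid,
        protein_identity=res.identity,
        frameshift_count=res.frameshift_count,
        has_stop=res.has_stop,
        is_target=(rid in target_ids) and not res.has_stop,
        score=res.score,
        ref_positions=list(res.ref_positions or []),
    )


@dataclass
class DiscriminationTally:
    retained: int = 0
    non_target: int = 0
    stop_codon: int = 0
    failed_alignment: int = 0

    @property
    def input_total(self) -> int:
        return self.retained + self.non_target + self.stop_codon + self.failed_alignment

    @property
    def pass_rate(self) -> float:
        n = self.input_total
        return self.retained / n if n else 0.0


def discriminate_targets(
    corrected: list[CorrectedAmplicon],
    failure_flag_rate: float = 0.5,
) -> tuple[list[CorrectedAmplicon], dict[str, DiscriminationTally]]:
    """Retain target, stop-free amplicons; tally rejections per sample.

    Samples whose failure rate exceeds ``failure_flag_rate`` are logged as
    suspect (mirrors flagging of samples where correction fails wholesale).
    """
    tallies: dict[str, DiscriminationTally] = {}
    kept = []
    for c in corrected:
        t = tallies.setdefault(c.sample_id, DiscriminationTally())
        if c.score <= 0 or not c.corrected_protein:
            t.failed_alignment += 1
        elif c.has_stop:
            t.stop_codon += 1
        elif not c.is_target:
            t.non_target += 1
        else:
            t.retained += 1
            kept.append(c)
    for sample, t in tallies.items():
        if t.input_total and (1 - t.pass_rate) > failure_flag_rate:
            log.warning(
                "sample %s: %.1f%% of reads rejected — flagged for review",
                sample, 100 * (1 - t.pass_rate),
            )
    return kept, tallies


# ---------------------------------------------------------------------------
# Clustering


@dataclass
class ClusterTable:
    """Sample x cluster count matrix with representatives."""

    identity_cutoff: float
    matrix: pd.DataFrame  # index: sample_id, columns: cluster ids
    representative_nt: dict[str, str] = field(default_factory=dict)
    contains_reference: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return self.matrix.shape[1]

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.matrix.sum(axis=1)
        return self.matrix.div(totals.replace(0, np.nan), axis=0).fillna(0.0)

    def filter_min_count(self, min_count: int = 5) -> "ClusterTable":
        keep = self.matrix.columns[self.matrix.sum(axis=0) >= min_count]
        return ClusterTable(
            identity_cutoff=self.identity_cutoff,
            matrix=self.matrix[keep].copy(),
            representative_nt={c: self.representative_nt[c] for c in keep if c in self.representative_nt},
            contains_reference={c: v for c, v in self.contains_reference.items() if c in keep},
        )


def _codon_row_from_correction(
    c: CorrectedAmplicon, residue_columns: list[int], n_columns: int
) -> str:
    """Project a corrected amplicon onto the model's match columns.

    The read's codons are placed at the model columns of the reference
    residues they were aligned to during frameshift correction, composing
    the read-to-reference and reference-to-model alignments.  Codons
    inserted relative to the reference, and codons whose reference residue
    sits in an insert state, are dropped.
    """
    row = ["---"] * n_columns
    for k, j in enumerate(c.ref_positions):
        if j < 0 or j >= len(residue_columns):
            continue
        col = residue_columns[j]
        if col > 0:
            row[col - 1] = c.corrected_nt[3 * k : 3 * k + 3]
    return "".join(row)


def cluster_amplicons(
    corrected: list[CorrectedAmplicon],
    model: ProfileModel,
    reference_proteins: dict[str, str],
    identity_cutoff: float = 0.90,
    reference_nt: dict[str, str] | None = None,
) -> ClusterTable:
    """Complete-linkage clustering of corrected amplicons at a nt identity.

    Each amplicon's codons are placed into model-column coordinates through
    its correction alignment (read -> closest reference) composed with the
    reference panel's model alignment, yielding a codon alignment of all
    amplicons without per-read realignment.  Distances ignore gap-gap
    columns and count residue-vs-gap as a difference.  References listed in
    ``reference_nt`` are co-clustered (trimmed to the model region) to
    label clusters by reference membership; they contribute no counts.
    """
    refs_nt = reference_nt or {}
    panel_ids = sorted({c.closest_ref_id for c in corrected} | set(refs_nt))
    panel_ids = [rid for rid in panel_ids if rid in reference_proteins]
    if not corrected or not panel_ids:
        return ClusterTable(identity_cutoff, pd.DataFrame())
    recs = {
        r.sequence_id: r
        for r in model.align([(rid, reference_proteins[rid]) for rid in panel_ids])
    }
    m = model.consensus_length
    # unique projected rows -> member amplicons
    uniq: dict[str, list[CorrectedAmplicon]] = {}
    for c in corrected:
        rec = recs.get(c.closest_ref_id)
        if rec is None:
            continue
        row = _codon_row_from_correction(c, rec.residue_columns, m)
        uniq.setdefault(row, []).append(c)
    entries = [(f"u{i:06d}", row) for i, row in enumerate(sorted(uniq))]
    ref_rows = {}
    for rid in sorted(refs_nt):
        rec = recs[rid]
        row = ["---"] * m
        for j, col in enumerate(rec.residue_columns):
            if col > 0 and 3 * j + 3 <= len(refs_nt[rid]):
                row[col - 1] = refs_nt[rid][3 * j : 3 * j + 3]
        ref_rows[f"ref:{rid}"] = "".join(row)
    all_ids = [uid for uid, _ in entries] + sorted(ref_rows)
    all_rows = [row for _, row in entries] + [ref_rows[r] for r in sorted(ref_rows)]
    dist = _cluster.distance_matrix(all_rows)
    clusters = _cluster.complete_linkage(all_ids, dist, identity_cutoff)

    row_of = dict(entries)
    samples = sorted({c.sample_id for c in corrected})
    counts: dict[str, dict[str, int]] = {}
    rep_nt: dict[str, str] = {}
    has_ref: dict[str, list[str]] = {}
    cluster_names = []
    for k, members in enumerate(clusters):
        amplicon_members = [x for x in members if not x.startswith("ref:")]
        ref_members = [x[4:] for x in members if x.startswith("ref:")]
        if not amplicon_members:
            continue
        name = f"cl{k:04d}"
        cluster_names.append(name)
        col = {s: 0 for s in samples}
        best_rep = None
        for uid in amplicon_members:
            group = uniq[row_of[uid]]
            for c in group:
                col[c.sample_id] += 1
            # representative: most abundant member sequence, ties by sequence
            nt_counts: dict[str, int] = {}
            for c in group:
                nt_counts[c.corrected_nt] = nt_counts.get(c.corrected_nt, 0) + 1
            for nt, n in nt_counts.items():
                if best_rep is None or (n, nt) > best_rep:
                    best_rep = (n, nt)
        counts[name] = col
        rep_nt[name] = best_rep[1]
        if ref_members:
            has_ref[name] = sorted(ref_members)
    matrix = pd.DataFrame(
        {name: [counts[name][s] for s in samples] for name in cluster_names},
        index=pd.Index(samples, name="sample_id"),
    )
    return ClusterTable(identity_cutoff, matrix, rep_nt, has_ref)


def rarefy(table: ClusterTable, depth: int, seed: int) -> ClusterTable:
    """Seeded subsampling without replacement to equal depth per sample."""
    totals = table.matrix.sum(axis=1)
    if (totals < depth).any():
        low = totals[totals < depth].index[0]
        raise ValueError(f"sample {low} has fewer than {depth} sequences")
    rng = np.random.default_rng(seed)
    out = table.matrix.copy()
    for s in table.matrix.index:
        row = table.matrix.loc[s].to_numpy()
        if row.sum() == depth:
            continue
        out.loc[s] = rng.multivariate_hypergeometric(row, depth)
    return ClusterTable(table.identity_cutoff, out, dict(table.representative_nt), dict(table.contains_reference))


# ---------------------------------------------------------------------------
# Diversity and identity summaries


PREVALENCE_BINS = [(0.0, 0.10, "<10%"), (0.10, 0.50, "10-50%"), (0.50, 0.90, "50-90%"), (0.90, 1.01, ">90%")]


def diversity_profile(tables: dict[float, ClusterTable]) -> pd.DataFrame:
    """Cluster counts, per-sample richness and prevalence-category shares
    per identity cutoff."""
    rows = []
    for cutoff in sorted(tables, reverse=True):
        t = tables[cutoff]
        present = t.matrix > 0
        per_sample = present.sum(axis=1)
        prevalence = present.mean(axis=0)
        seq_per_cluster = t.matrix.sum(axis=0)
        total_seqs = seq_per_cluster.sum()
        row = {
            "identity_cutoff": cutoff,
            "total_clusters": int(t.n_clusters),
            "clusters_per_sample_mean": float(per_sample.mean()),
            "clusters_per_sample_sd": float(per_sample.std(ddof=1)) if len(per_sample) > 1 else 0.0,
        }
        for lo, hi, label in PREVALENCE_BINS:
            in_bin = (prevalence > lo) & (prevalence <= hi) if lo > 0 else (prevalence <= hi)
            row[f"clusters_{label}"] = float(in_bin.mean()) if t.n_clusters else 0.0
            row[f"sequences_{label}"] = (
                float(seq_per_cluster[in_bin].sum() / total_seqs) if total_seqs else 0.0
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _edlib_identity(query: str, target: str) -> float:
    if not query or not target:
        return 0.0
    res = edlib.align(query, target, mode="HW", task="path")
    if res["editDistance"] < 0:
        return 0.0
    cigar = res["cigar"] or ""
    cols = eq = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            cols += n
            if ch == "=":
                eq += n
    return eq / cols if cols else 0.0


def best_match_identity(
    corrected: list[CorrectedAmplicon], target_nt: dict[str, str]
) -> pd.DataFrame:
    """Per read: the maximum nucleotide identity to any target reference."""
    rows = []
    for c in corrected:
        best = 0.0
        best_ref = ""
        for rid in sorted(target_nt):
            ident = max(
                _edlib_identity(c.corrected_nt, target_nt[rid]),
                _edlib_identity(target_nt[rid], c.corrected_nt),
            )
            if ident > best:
                best, best_ref = ident, rid
        rows.append({"read_id": c.read_id, "sample_id": c.sample_id, "identity": best, "ref_id": best_ref})
    return pd.DataFrame(rows, columns=["read_id", "sample_id", "identity", "ref_id"])


# ---------------------------------------------------------------------------
# Co-occurrence network


@dataclass
class CooccurrenceNetwork:
    graph: nx.Graph
    tested_pairs: int

    @property
    def edges(self) -> list[tuple[str, str, dict]]:
        return [(u, v, d) for u, v, d in self.graph.edges(data=True)]


def cooccurrence(
    table: ClusterTable,
    prevalence_min: float = 0.5,
    rho_min: float = 0.5,
    p_max: float = 0.01,
    q_max: float = 0.01,
) -> CooccurrenceNetwork:
    """Spearman co-occurrence network on relative cluster abundances.

    Only clusters present in at least ``prevalence_min`` of samples are
    tested; p-values use the t approximation with midranks; q-values are
    Benjamini-Hochberg over all tested pairs; an edge needs rho >= rho_min,
    p < p_max and q < q_max.
    """
    n_samples = table.matrix.shape[0]
    if n_samples < 4:
        raise ValueError("co-occurrence analysis needs at least 4 samples")
    rel = table.relative_abundance()
    prevalence = (table.matrix > 0).mean(axis=0)
    keep = [c for c in table.matrix.columns if prevalence[c] >= prevalence_min]
    g = nx.Graph()
    for c in keep:
        g.add_node(c, prevalence=float(prevalence[c]), mean_relative_abundance=float(rel[c].mean()))
    pairs = [(a, b) for i, a in enumerate(keep) for b in keep[i + 1 :]]
    if not pairs:
        return CooccurrenceNetwork(g, 0)
    stats = []
    for a, b in pairs:
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            rho, p = spearmanr(rel[a], rel[b])
        if not np.isfinite(rho):  # constant input: no association testable
            rho, p = 0.0, 1.0
        stats.append((a, b, float(rho), float(p)))
    _, qvals, _, _ = multipletests([p for *_, p in stats], method="fdr_bh")
    for (a, b, rho, p), q in zip(stats, qvals):
        if rho >= rho_min and p < p_max and q < q_max:
            g.add_edge(a, b, rho=rho, p=p, q=float(q))
    return CooccurrenceNetwork(g, len(pairs))


# ---------------------------------------------------------------------------
# Ordination


@dataclass
class Ordination:
    coordinates: pd.DataFrame  # index sample, columns dim1, dim2
    stress: float
    dissimilarity: pd.DataFrame


def ordinate(table: ClusterTable, seed: int = 0, n_init: int = 16, max_iter: int = 500) -> Ordination:
    """Non-metric MDS on Bray-Curtis dissimilarities of relative abundances."""
    rel = table.relative_abundance()
    d = squareform(pdist(rel.to_numpy(), metric="braycurtis"))
    d = np.nan_to_num(d, nan=0.0)
    mds = MDS(
        n_components=2,
        metric_mds=False,
        metric="precomputed",
        init="random",
        random_state=seed,
        n_init=n_init,
        max_iter=max_iter,
        normalized_stress=True,
    )
    coords = mds.fit_transform(d)
    return Ordination(
        coordinates=pd.DataFrame(coords, index=rel.index, columns=["dim1", "dim2"]),
        stress=float(mds.stress_),
        dissimilarity=pd.DataFrame(d, index=rel.index, columns=rel.index),
    )


# ---------------------------------------------------------------------------
# End-to-end orchestration


@dataclass
class AmpliconRunResult:
    corrected: list[CorrectedAmplicon]
    retained: list[CorrectedAmplicon]
    tallies: dict[str, DiscriminationTally]
    tables: dict[float, ClusterTable]
    diversity: pd.DataFrame
    identity_summary: pd.DataFrame


def run_amplicon_pipeline(
    reads_by_sample: dict[str, list[formats.Read]],
    reference_proteins: dict[str, str],
    target_ids: set[str],
    model: ProfileModel,
    target_nt: dict[str, str] | None = None,
    identity_cutoffs: tuple[float, ...] = (0.99, 0.98, 0.95, 0.90),
    min_count: int = 5,
    rarefy_depth: int | None = None,
    seed: int = 0,
    params: FrameshiftParams | None = None,
) -> AmpliconRunResult:
    """Correct, discriminate and cluster merged amplicon reads per sample.

    ``reference_proteins`` must contain the target uniques plus the
    below-threshold outgroup so non-target amplicons are rejected rather
    than force-assigned.
    """
    corrected: list[CorrectedAmplicon] = []
    for sample in sorted(reads_by_sample):
        for read in reads_by_sample[sample]:
            if len(read.sequence) < 3:
                continue
            corrected.append(
                frameshift_correct(
                    read.sequence, reference_proteins, target_ids,
                    read_id=read.read_id, sample_id=sample, params=params,
                )
            )
    retained, tallies = discriminate_targets(corrected)
    tables: dict[float, ClusterTable] = {}
    for cutoff in identity_cutoffs:
        t = cluster_amplicons(
            retained, model, reference_proteins, identity_cutoff=cutoff
        )
        t = t.filter_min_count(min_count)
        if rarefy_depth:
            t = rarefy(t, rarefy_depth, seed)
        tables[cutoff] = t
    div = diversity_profile(tables)
    ident = (
        best_match_identity(retained, target_nt)
        if target_nt
        else pd.DataFrame(columns=["read_id", "sample_id", "identity", "ref_id"])
    )
    return AmpliconRunResult(
        corrected=corrected,
        retained=retained,
        tallies=tallies,
        tables=tables,
        diversity=div,
        identity_summary=ident,
    )
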