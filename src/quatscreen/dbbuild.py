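"""Multi-parametric genome screen and gene reference-database assembly.

The screen takes annotated genomes and a seed protein alignment of a target
enzyme family (e.g. choline TMA-lyase CutC, carnitine oxygenase CntA) and
ranks every encoded protein by its similarity to a profile model.  Unique
proteins are then put through a battery of orthogonal criteria:

* model coverage (partial sequences below 80% of model columns are dropped),
* conserved signature residues (e.g. the CntA "bridging" glutamate),
* phylogenetic (cophenetic) distance to the top-scoring sequence,
* synteny with the pathway partner gene (cutD / cntB) within a bounded
  locus-tag separation,
* a score cutoff placed at the largest relative drop of the ranked scores.

Everything above the cutoff (minus phylogeny-flagged outliers) becomes the
target reference set; the top-scoring below-cutoff uniques are retained as
an outgroup so that downstream read/amplicon classification can *reject*
near-miss homologs instead of mis-assigning them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj

from . import cluster as _cluster
from . import formats
from .formats import FeatureRecord, GenomeRecord
from .profile import AlignmentRecord, ProfileModel

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class SignatureRule:
    """Residue constraint at a model match column (1-based)."""

    model_column: int
    allowed_residues: frozenset[str]
    label: str


@dataclass
class SyntenyResult:
    partner_found: bool
    locus_separation: int | None
    same_contig: bool


@dataclass
class Hit:
    genome_id: str
    feature: FeatureRecord
    score: float

    @property
    def protein(self) -> str:
        return self.feature.protein

    @property
    def gene_nt(self) -> str:
        return self.feature.gene_nt


@dataclass
class Candidate:
    """One unique protein with its full criterion record (a Fig.-style row)."""

    protein_id: str
    protein: str
    score: float
    members: list[Hit] = field(default_factory=list)
    coverage: float = 0.0
    residues_ok: dict[str, bool] = field(default_factory=dict)
    phylo_dist_to_top: float = float("nan")
    synteny: SyntenyResult | None = None
    status: str = "unassigned"  # target | below_cutoff | excluded_by_phylogeny | partial

    @property
    def member_genome_ids(self) -> list[str]:
        return sorted({h.genome_id for h in self.members})

    @property
    def representative(self) -> Hit:
        return min(self.members, key=lambda h: (h.genome_id, h.feature.contig_id, h.feature.locus_index))


@dataclass
class Reference:
    ref_id: str
    nt: str
    protein: str
    taxonomy: str = ""
    cluster90: str = ""


@dataclass
class GeneDatabase:
    """Target and outgroup references for one gene, plus build metadata."""

    gene_name: str
    target_refs: list[Reference]
    outgroup_protein_refs: list[Reference]
    outgroup_nt_refs: list[Reference]
    cutoff_used: float
    copy_number: dict[str, int] = field(default_factory=dict)
    multi_copy_nonidentical: list[str] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)

    def target_proteins(self) -> dict[str, str]:
        return {r.ref_id: r.protein for r in self.target_refs}

    def target_nt(self) -> dict[str, str]:
        return {r.ref_id: r.nt for r in self.target_refs}

    def outgroup_proteins(self) -> dict[str, str]:
        return {r.ref_id: r.protein for r in self.outgroup_protein_refs}

    def outgroup_nt(self) -> dict[str, str]:
        return {r.ref_id: r.nt for r in self.outgroup_nt_refs}

    def save(self, db_dir: str | Path) -> None:
        db_dir = Path(db_dir)
        db_dir.mkdir(parents=True, exist_ok=True)
        formats.write_fasta([(r.ref_id, r.protein) for r in self.target_refs], db_dir / "targets.faa")
        formats.write_fasta([(r.ref_id, r.nt) for r in self.target_refs], db_dir / "targets.fna")
        formats.write_fasta(
            [(r.ref_id, r.protein) for r in self.outgroup_protein_refs], db_dir / "outgroup.faa"
        )
        formats.write_fasta([(r.ref_id, r.nt) for r in self.outgroup_nt_refs], db_dir / "outgroup.fna")
        formats.write_json(
            {
                "gene_name": self.gene_name,
                "cutoff_used": self.cutoff_used,
                "copy_number": self.copy_number,
                "multi_copy_nonidentical": self.multi_copy_nonidentical,
                "parameters": self.parameters,
                "taxonomy": {r.ref_id: r.taxonomy for r in self.target_refs},
                "cluster90": {r.ref_id: r.cluster90 for r in self.target_refs},
            },
            db_dir / "db.json",
        )

    @classmethod
    def load(cls, db_dir: str | Path) -> "GeneDatabase":
        db_dir = Path(db_dir)
        meta = formats.read_json(db_dir / "db.json")
        faa = formats.read_fasta(db_dir / "targets.faa")
        fna = formats.read_fasta(db_dir / "targets.fna")
        out_faa = formats.read_fasta(db_dir / "outgroup.faa")
        out_fna = formats.read_fasta(db_dir / "outgroup.fna")
        tax = meta.get("taxonomy", {})
        c90 = meta.get("cluster90", {})
        targets = [
            Reference(rid, fna.get(rid, ""), faa.get(rid, ""), tax.get(rid, ""), c90.get(rid, ""))
            for rid in faa
        ]
        return cls(
            gene_name=meta["gene_name"],
            target_refs=targets,
            outgroup_protein_refs=[Reference(rid, "", seq) for rid, seq in out_faa.items()],
            outgroup_nt_refs=[Reference(rid, seq, "") for rid, seq in out_fna.items()],
            cutoff_used=float(meta["cutoff_used"]),
            copy_number={k: int(v) for k, v in meta.get("copy_number", {}).items()},
            multi_copy_nonidentical=list(meta.get("multi_copy_nonidentical", [])),
            parameters=meta.get("parameters", {}),
        )


# ---------------------------------------------------------------------------
# Screening steps


def screen_genomes(
    genomes: list[GenomeRecord], model: ProfileModel, top_n: int | None = None
) -> list[Hit]:
    """Score every encoded protein and keep the ``top_n`` by bit score.

    Ties are broken by (genome_id, contig_id, locus_index) so the ranking is
    deterministic.  Duplicate genome records (same genome_id) are collapsed.
    """
    seen: set[str] = set()
    entries: list[tuple[str, FeatureRecord]] = []
    for g in genomes:
        if g.genome_id in seen:
            continue
        seen.add(g.genome_id)
        for f in g.features:
            if f.protein:
                entries.append((g.genome_id, f))
    if not entries or top_n == 0:
        return []
    keyed = [
        (f"{gid}|{f.contig_id}|{f.locus_index}", f.protein) for gid, f in entries
    ]
    scores = model.score_sequences(keyed)
    hits = [
        Hit(genome_id=gid, feature=f, score=scores[f"{gid}|{f.contig_id}|{f.locus_index}"])
        for gid, f in entries
    ]
    hits = [h for h in hits if np.isfinite(h.score)]
    hits.sort(key=lambda h: (-h.score, h.genome_id, h.feature.contig_id, h.feature.locus_index))
    return hits if top_n is None else hits[:top_n]


def dereplicate(hits: list[Hit]) -> list[Candidate]:
    """Collapse hits to unique amino-acid strings, keeping all members."""
    groups: dict[str, list[Hit]] = {}
    for h in hits:
        groups.setdefault(h.protein, []).append(h)
    candidates = []
    for protein, members in groups.items():
        members = sorted(members, key=lambda h: (h.genome_id, h.feature.contig_id, h.feature.locus_index))
        rep = members[0]
        candidates.append(
            Candidate(
                protein_id=f"{rep.genome_id}.{rep.feature.locus_tag}",
                protein=protein,
                score=max(h.score for h in members),
                members=members,
            )
        )
    candidates.sort(key=lambda c: (-c.score, c.protein_id))
    return candidates


def check_signatures(
    record: AlignmentRecord, rules: list[SignatureRule]
) -> dict[str, bool]:
    """True per rule iff the residue aligned to the rule's model column is
    allowed; a deletion at that column fails the rule."""
    flags = {}
    for rule in rules:
        residue = record.residue_at(rule.model_column)
        flags[rule.label] = residue in rule.allowed_residues
    return flags


def _p_distance_matrix(rows: list[str]) -> np.ndarray:
    return _cluster.distance_matrix(rows)


def phylo_distance_to_top(
    aligned: list[tuple[str, str]], top_id: str
) -> dict[str, float]:
    """Tree path-length (cophenetic) distance from every tip to the top tip.

    A neighbor-joining tree is built on p-distances over shared aligned
    columns; with fewer than 3 sequences the p-distances themselves are
    returned.  On additive distance matrices NJ path lengths reproduce the
    input distances exactly.
    """
    ids = [sid for sid, _ in aligned]
    if top_id not in ids:
        raise ValueError(f"top sequence {top_id!r} not in alignment")
    rows = [row for _, row in aligned]
    if len(ids) < 3:
        d = _p_distance_matrix(rows)
        k = ids.index(top_id)
        return {sid: float(d[k, i]) for i, sid in enumerate(ids)}
    dm = DistanceMatrix(_p_distance_matrix(rows), ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tree = nj(dm)
    cope = tree.tip_tip_distances()
    out = {}
    for sid in ids:
        out[sid] = 0.0 if sid == top_id else max(0.0, float(cope[top_id, sid]))
    return out


def check_synteny(
    genome: GenomeRecord,
    hit_feature: FeatureRecord,
    partner_model: ProfileModel,
    partner_cutoff: float,
    max_separation: int = 10,
) -> SyntenyResult:
    """Look for the pathway partner gene near a hit, by locus-tag order.

    The partner is found iff some *other* feature on the hit's contig scores
    at least ``partner_cutoff`` bits against the partner model and lies
    within ``max_separation`` intervening locus indices.
    """
    contig_feats = [
        f
        for f in genome.features_on(hit_feature.contig_id)
        if f.locus_index != hit_feature.locus_index and f.protein
    ]
    if not contig_feats:
        return SyntenyResult(False, None, False)
    keyed = [(str(i), f.protein) for i, f in enumerate(contig_feats)]
    scores = partner_model.score_sequences(keyed)
    best_sep: int | None = None
    found = False
    for i, f in enumerate(contig_feats):
        if scores[str(i)] >= partner_cutoff:
            sep = abs(f.locus_index - hit_feature.locus_index)
            if best_sep is None or sep < best_sep:
                best_sep = sep
            if sep <= max_separation:
                found = True
    return SyntenyResult(partner_found=found, locus_separation=best_sep, same_contig=best_sep is not None)


def partner_cutoff_from_top(
    genomes: list[GenomeRecord], partner_model: ProfileModel, fraction: float
) -> float:
    """Partner score threshold as a fraction of the top partner score."""
    hits = screen_genomes(genomes, partner_model, top_n=1)
    if not hits:
        raise ValueError("no partner-gene hits found in the genome set")
    return fraction * hits[0].score


def detect_cutoff(scores: list[float], mode: str = "auto", value: float | None = None) -> float:
    """Place the score cutoff at the largest relative drop of ranked scores.

    ``scores`` must be sorted descending.  The drop is searched within the
    interior ranks 2..N-1: neither the single top score nor the single
    bottom score anchors a drop (a true family/homolog boundary separates
    groups, while the extremes reflect individual outliers; relative drops
    in particular blow up at the low-score tail).  The cutoff is the median
    of the two scores framing the winning drop, i.e. their mean.  With
    ``mode='manual'`` the supplied value is echoed.
    """
    if mode == "manual":
        if value is None:
            raise ValueError("manual mode requires a value")
        return float(value)
    if mode != "auto":
        raise ValueError(f"unknown cutoff mode {mode!r}")
    if len(scores) < 2:
        raise ValueError("need at least 2 scores to place a cutoff")
    if any(scores[i] < scores[i + 1] for i in range(len(scores) - 1)):
        raise ValueError("scores must be sorted descending")
    best_drop = -1.0
    best_pair: tuple[float, float] | None = None
    if len(scores) <= 3:
        start, stop = 0, len(scores) - 1
    else:
        start, stop = 1, len(scores) - 2
    for i in range(start, stop):
        hi, lo = scores[i], scores[i + 1]
        if hi <= 0:
            continue
        drop = (hi - lo) / hi
        if drop > best_drop:
            best_drop = drop
            best_pair = (hi, lo)
    if best_pair is None or best_drop <= 0:
        raise ValueError("no drop detected; use manual cutoff mode")
    return (best_pair[0] + best_pair[1]) / 2.0


# ---------------------------------------------------------------------------
# Assembly


def assemble_database(
    candidates: list[Candidate],
    cutoff: float,
    gene_name: str = "gene",
    phylo_filter: bool = False,
    phylo_quantile: float = 0.95,
    outgroup_protein_size: int = 300,
    outgroup_nt_size: int = 500,
    taxonomy: dict[str, str] | None = None,
    model: ProfileModel | None = None,
    parameters: dict | None = None,
) -> GeneDatabase:
    """Turn fully evaluated candidates into a target + outgroup database.

    Targets are above-cutoff candidates; with the phylogeny filter on,
    above-cutoff candidates are excluded when their cophenetic distance to
    the top sequence exceeds the given quantile of target distances *and*
    their partner-gene synteny check failed (both conditions are logged).
    Outgroups are the top-scoring below-cutoff uniques — by unique protein
    for the amplicon reference set and by unique nucleotide sequence for the
    metagenome reference set.
    """
    taxonomy = taxonomy or {}
    above = [c for c in candidates if c.score >= cutoff and c.status != "partial"]
    below = [c for c in candidates if c.score < cutoff and c.status != "partial"]
    excluded: list[Candidate] = []
    if phylo_filter and above:
        dists = np.array([c.phylo_dist_to_top for c in above if np.isfinite(c.phylo_dist_to_top)])
        if dists.size:
            thresh = float(np.quantile(dists, phylo_quantile))
            kept = []
            for c in above:
                far = np.isfinite(c.phylo_dist_to_top) and c.phylo_dist_to_top > thresh
                no_synteny = c.synteny is not None and not c.synteny.partner_found
                if far and no_synteny:
                    log.info(
                        "phylogeny filter: excluding %s (dist %.4f > %.4f, no synteny)",
                        c.protein_id, c.phylo_dist_to_top, thresh,
                    )
                    c.status = "excluded_by_phylogeny"
                    excluded.append(c)
                else:
                    kept.append(c)
            above = kept
    for c in above:
        c.status = "target"
    for c in below:
        c.status = "below_cutoff"

    targets = [
        Reference(
            ref_id=c.protein_id,
            nt=c.representative.gene_nt,
            protein=c.protein,
            taxonomy=taxonomy.get(c.protein_id, ""),
        )
        for c in above
    ]
    # 90% nucleotide reference clusters of the targets (codon-aligned via the model)
    if model is not None and len(targets) >= 2:
        label_clusters_90(targets, model)

    def _unique_outgroup(key) -> list[Candidate]:
        seen, out = set(), []
        for c in below:
            k = key(c)
            if k and k not in seen:
                seen.add(k)
                out.append(c)
        return out

    og_prot = _unique_outgroup(lambda c: c.protein)[:outgroup_protein_size]
    og_nt = _unique_outgroup(lambda c: c.representative.gene_nt)[:outgroup_nt_size]
    if len(og_prot) < outgroup_protein_size or len(og_nt) < outgroup_nt_size:
        log.warning(
            "outgroup smaller than requested (%d proteins / %d nt available)",
            len(og_prot), len(og_nt),
        )
    outgroup_protein = [
        Reference(ref_id=c.protein_id, nt=c.representative.gene_nt, protein=c.protein)
        for c in og_prot
    ]
    outgroup_nt = [
        Reference(ref_id=c.protein_id, nt=c.representative.gene_nt, protein=c.protein)
        for c in og_nt
    ]

    copy_number: dict[str, int] = {}
    per_genome_seqs: dict[str, set[str]] = {}
    for c in above:
        for h in c.members:
            copy_number[h.genome_id] = copy_number.get(h.genome_id, 0) + 1
            per_genome_seqs.setdefault(h.genome_id, set()).add(h.protein)
    multi = sorted(
        g for g, n in copy_number.items() if n > 1 and len(per_genome_seqs[g]) > 1
    )
    return GeneDatabase(
        gene_name=gene_name,
        target_refs=targets,
        outgroup_protein_refs=outgroup_protein,
        outgroup_nt_refs=outgroup_nt,
        cutoff_used=float(cutoff),
        copy_number=copy_number,
        multi_copy_nonidentical=multi,
        parameters=parameters or {},
    )


def label_clusters_90(targets: list[Reference], model: ProfileModel, identity: float = 0.90) -> None:
    """Assign 90% complete-linkage nucleotide cluster labels to references.

    References are aligned to the model, the protein alignment is expanded
    to a codon alignment of the genes, and complete linkage is run on the
    resulting nucleotide identities.
    """
    from .profile import backtranslate_alignment

    recs = model.align([(r.ref_id, r.protein) for r in targets])
    rows = [(r.sequence_id, r.aligned_row.replace(".", "-").upper()) for r in recs]
    nt = {r.ref_id: r.nt for r in targets}
    try:
        codon_rows = backtranslate_alignment(rows, nt)
    except ValueError as exc:
        log.warning("skipping 90%% reference clustering: %s", exc)
        return
    ids = [rid for rid, _ in codon_rows]
    dist = _cluster.distance_matrix([row for _, row in codon_rows])
    clusters = _cluster.complete_linkage(ids, dist, identity)
    for k, members in enumerate(clusters):
        for rid in members:
            for r in targets:
                if r.ref_id == rid:
                    r.cluster90 = f"c90_{k:03d}"


# ---------------------------------------------------------------------------
# Candidate table


CANDIDATE_COLUMNS = [
    "protein_id",
    "score",
    "coverage",
    "phylo_dist_to_top",
    "synteny",
    "locus_separation",
    "residues_ok",
    "status",
    "n_members",
    "member_genomes",
]


def candidate_table(candidates: list[Candidate]) -> pd.DataFrame:
    rows = []
    for c in sorted(candidates, key=lambda c: (-c.score, c.protein_id)):
        rows.append(
            {
                "protein_id": c.protein_id,
                "score": c.score,
                "coverage": c.coverage,
                "phylo_dist_to_top": c.phylo_dist_to_top,
                "synteny": bool(c.synteny.partner_found) if c.synteny else False,
                "locus_separation": (
                    c.synteny.locus_separation if c.synteny and c.synteny.locus_separation is not None else -1
                ),
                "residues_ok": all(c.residues_ok.values()) if c.residues_ok else True,
                "status": c.status,
                "n_members": len(c.members),
                "member_genomes": ",".join(c.member_genome_ids),
            }
        )
    return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)


# ---------------------------------------------------------------------------
# Orchestration


def build_database(
    genomes: list[GenomeRecord],
    seed_alignment: list[tuple[str, str]],
    partner_seed_alignment: list[tuple[str, str]] | None = None,
    gene_name: str = "gene",
    signatures: list[SignatureRule] | None = None,
    top_n: int = 3000,
    min_coverage: float = 0.8,
    cutoff_mode: str = "auto",
    cutoff_value: float | None = None,
    partner_fraction: float = 0.5,
    max_separation: int = 10,
    phylo_filter: bool = False,
    phylo_quantile: float = 0.95,
    refine_cycles: int = 3,
    outgroup_protein_size: int = 300,
    outgroup_nt_size: int = 500,
    taxonomy: dict[str, str] | None = None,
) -> tuple[GeneDatabase, pd.DataFrame, ProfileModel]:
    """Run the full screen and return (database, candidate table, model)."""
    model = ProfileModel.from_alignment(seed_alignment, name=gene_name)
    if refine_cycles:
        model = model.refine(seed_alignment, cycles=refine_cycles)
    hits = screen_genomes(genomes, model, top_n=top_n)
    candidates = dereplicate(hits)
    records = model.align([(c.protein_id, c.protein) for c in candidates])
    rec_of = {r.sequence_id: r for r in records}
    for c in candidates:
        c.coverage = rec_of[c.protein_id].coverage
        if c.coverage < min_coverage:
            c.status = "partial"
        if signatures:
            c.residues_ok = check_signatures(rec_of[c.protein_id], signatures)
    full = [c for c in candidates if c.status != "partial"]
    if len(full) >= 2:
        aligned = [
            (c.protein_id, "".join(rec_of[c.protein_id].residue_at(k) for k in range(1, model.consensus_length + 1)))
            for c in full
        ]
        top_id = full[0].protein_id
        dists = phylo_distance_to_top(aligned, top_id)
        for c in full:
            c.phylo_dist_to_top = dists[c.protein_id]
    partner_model = None
    if partner_seed_alignment:
        partner_model = ProfileModel.from_alignment(partner_seed_alignment, name=f"{gene_name}_partner")
        if refine_cycles:
            partner_model = partner_model.refine(partner_seed_alignment, cycles=refine_cycles)
        partner_cutoff = partner_cutoff_from_top(genomes, partner_model, partner_fraction)
        genome_of = {g.genome_id: g for g in genomes}
        for c in full:
            rep = c.representative
            c.synteny = check_synteny(
                genome_of[rep.genome_id], rep.feature, partner_model, partner_cutoff, max_separation
            )
    scores = [c.score for c in full]
    cutoff = detect_cutoff(scores, mode=cutoff_mode, value=cutoff_value)
    db = assemble_database(
        full,
        cutoff,
        gene_name=gene_name,
        phylo_filter=phylo_filter,
        phylo_quantile=phylo_quantile,
        outgroup_protein_size=outgroup_protein_size,
        outgroup_nt_size=outgroup_nt_size,
        taxonomy=taxonomy,
        model=model,
        parameters={
            "top_n": top_n,
            "min_coverage": min_coverage,
            "cutoff_mode": cutoff_mode,
            "partner_fraction": partner_fraction,
            "max_separation": max_separation,
            "phylo_filter": phylo_filter,
            "refine_cycles": refine_cycles,
        },
    )
    table = candidate_table(candidates)
    return db, table, model


def save_build(
    db: GeneDatabase, table: pd.DataFrame, model: ProfileModel, db_dir: str | Path
) -> None:
    """Write a build's database, candidate table and profile model."""
    db_dir = Path(db_dir)
    db.save(db_dir)
    formats.write_candidate_table(table, db_dir / "candidates.tsv")
    model.save(db_dir / "model.hmm")


def read_signatures_tsv(path: str | Path) -> dict[str, list[SignatureRule]]:
    """Signature rules grouped by gene from a TSV
    (gene, model_column, allowed_residues, label)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    rules: dict[str, list[SignatureRule]] = {}
    for _, row in df.iterrows():
        rules.setdefault(str(row["gene"]), []).append(
            SignatureRule(
                model_column=int(row["model_column"]),
                allowed_residues=frozenset(str(row["allowed_residues"]).upper()),
                label=str(row["label"]),
            )
        )
    return rules
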