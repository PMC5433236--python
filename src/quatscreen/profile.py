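"""Position-specific profile models of protein families.

A :class:`ProfileModel` is built from a seed protein alignment, can be
iteratively refined (realign seeds, rebuild, repeat), scores sequences in
bits, aligns batches of sequences back to the model and reports per-sequence
model coverage.  The heavy lifting is delegated to the HMMER3 engine through
pyhmmer; the surface here is engine-agnostic and tests only rely on the
contract (determinism, coverage semantics, relative score ordering).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pyhmmer
from pyhmmer.easel import Alphabet, DigitalSequenceBlock, TextMSA, TextSequence
from pyhmmer.plan7 import Background, Builder, HMMFile, Pipeline

from . import formats

log = logging.getLogger(__name__)


def _as_str(name) -> str:
    return name if isinstance(name, str) else name.decode()

NEG_INF = float("-inf")
_ALPHABET = Alphabet.amino()


@dataclass
class AlignmentRecord:
    """A sequence aligned to a profile model.

    ``model_residues`` maps 1-based match-column index -> residue ('-' for a
    deletion).  ``coverage`` is the fraction of model columns occupied by a
    residue.
    """

    sequence_id: str
    model_residues: dict[int, str]
    coverage: float
    score: float
    aligned_row: str = ""
    residue_columns: list[int] = field(default_factory=list)
    """Per residue of the input sequence: its 1-based match column, or -1
    when the residue sits in an insert state."""

    def residue_at(self, column: int) -> str:
        return self.model_residues.get(column, "-")


def _text_msa(sequences: list[tuple[str, str]], name: bytes = b"seed") -> TextMSA:
    return TextMSA(
        name=name,
        sequences=[
            TextSequence(name=str(sid).encode(), sequence=seq)
            for sid, seq in sequences
        ],
    )


def _digitize(sequences: list[tuple[str, str]]) -> DigitalSequenceBlock:
    seqs = [
        TextSequence(name=str(sid).encode(), sequence=seq).digitize(_ALPHABET)
        for sid, seq in sequences
    ]
    return DigitalSequenceBlock(_ALPHABET, seqs)


@dataclass
class ProfileModel:
    """Profile of a protein family, scored in log-odds bits."""

    hmm: "pyhmmer.plan7.HMM"
    seed_ids: list[str] = field(default_factory=list)
    refine_cycles: int = 0

    # -- construction -------------------------------------------------------

    @classmethod
    def from_alignment(
        cls, seed_alignment: list[tuple[str, str]], name: str = "profile"
    ) -> "ProfileModel":
        """Build a model from an aligned set of >=2 equal-length sequences.

        Match columns are the alignment columns below the builder's gap
        threshold; emissions are pseudocount-smoothed log-odds against the
        background amino-acid frequencies.
        """
        if len(seed_alignment) < 2:
            raise ValueError("seed alignment needs at least 2 sequences")
        lengths = {len(s) for _, s in seed_alignment}
        if len(lengths) != 1:
            raise ValueError("seed alignment rows must have equal aligned length")
        msa = _text_msa(seed_alignment, name=name.encode()).digitize(_ALPHABET)
        builder = Builder(_ALPHABET)
        hmm, _, _ = builder.build_msa(msa, Background(_ALPHABET))
        return cls(hmm=hmm, seed_ids=[sid for sid, _ in seed_alignment])

    # -- basic properties ----------------------------------------------------

    @property
    def consensus_length(self) -> int:
        return self.hmm.M

    @property
    def consensus(self) -> str:
        return (self.hmm.consensus or "").upper()

    def emission_logodds(self) -> np.ndarray:
        """Match-state emission log-odds (bits) vs the background, one row
        per match column over the 20 canonical residues."""
        bg = Background(_ALPHABET).residue_frequencies.copy()
        em = np.asarray(self.hmm.match_emissions)[1:, :20]
        bgv = np.asarray(list(bg))[:20]
        return np.log2(np.clip(em, 1e-12, None) / bgv)

    # -- scoring -------------------------------------------------------------

    def _pipeline(self) -> Pipeline:
        # All heuristic filters off so that scoring is exact and monotone in
        # the model; reporting threshold wide open so weak sequences still
        # return their true bit score.
        return Pipeline(
            _ALPHABET,
            Background(_ALPHABET),
            bias_filter=False,
            F1=1.0,
            F2=1.0,
            F3=1.0,
            E=1e9,
            domE=1e9,
        )

    def score_sequences(self, proteins: list[tuple[str, str]]) -> dict[str, float]:
        """Best local bit score per sequence; -inf when nothing aligns."""
        scores = {str(sid): NEG_INF for sid, _ in proteins}
        nonempty = [(sid, seq) for sid, seq in proteins if seq]
        if not nonempty:
            return scores
        hits = self._pipeline().search_hmm(self.hmm, _digitize(nonempty))
        for hit in hits:
            scores[_as_str(hit.name)] = float(hit.score)
        return scores

    def score_sequence(self, protein: str) -> float:
        if not protein:
            return NEG_INF
        return self.score_sequences([("q", protein)])["q"]

    def search_coverage(self, proteins: list[tuple[str, str]]) -> dict[str, float]:
        """Fraction of model columns spanned by the best-scoring domain."""
        cov = {str(sid): 0.0 for sid, _ in proteins}
        nonempty = [(sid, seq) for sid, seq in proteins if seq]
        if not nonempty:
            return cov
        hits = self._pipeline().search_hmm(self.hmm, _digitize(nonempty))
        for hit in hits:
            dom = hit.best_domain
            ali = dom.alignment
            cov[_as_str(hit.name)] = (ali.hmm_to - ali.hmm_from + 1) / self.hmm.M
        return cov

    # -- alignment -----------------------------------------------------------

    def align(self, proteins: list[tuple[str, str]]) -> list[AlignmentRecord]:
        """Align sequences to the model; coverage counts occupied match columns."""
        records: list[AlignmentRecord] = []
        nonempty = [(sid, seq) for sid, seq in proteins if seq]
        empty_ids = [sid for sid, seq in proteins if not seq]
        scores = self.score_sequences(nonempty) if nonempty else {}
        if nonempty:
            msa = pyhmmer.hmmer.hmmalign(self.hmm, _digitize(nonempty), trim=False)
            ref = msa.reference or ""
            match_cols = [i for i, c in enumerate(ref) if c.lower() == "x"]
            match_set = set(match_cols)
            for name, row in zip(msa.names, msa.alignment):
                sid = _as_str(name)
                model_residues: dict[int, str] = {}
                occupied = 0
                for k, col in enumerate(match_cols, start=1):
                    c = row[col]
                    if c.isalpha():
                        model_residues[k] = c.upper()
                        occupied += 1
                    else:
                        model_residues[k] = "-"
                residue_columns: list[int] = []
                k = 0
                for col, c in enumerate(row):
                    is_match = col in match_set
                    if is_match:
                        k += 1
                    if c.isalpha():
                        residue_columns.append(k if is_match else -1)
                records.append(
                    AlignmentRecord(
                        sequence_id=sid,
                        model_residues=model_residues,
                        coverage=occupied / max(1, len(match_cols)),
                        score=scores.get(sid, NEG_INF),
                        aligned_row=row,
                        residue_columns=residue_columns,
                    )
                )
        for sid in empty_ids:
            records.append(AlignmentRecord(str(sid), {}, 0.0, NEG_INF))
        order = {str(sid): i for i, (sid, _) in enumerate(proteins)}
        records.sort(key=lambda r: order[r.sequence_id])
        return records

    def match_alignment_rows(
        self, proteins: list[tuple[str, str]]
    ) -> list[tuple[str, str]]:
        """Each sequence rendered over the model's match columns only
        (equal-length rows; deletions as '-'); insert states are dropped.
        Suitable input for distance computation and back-translation-based
        clustering of the model-aligned region."""
        recs = self.align(proteins)
        m = self.consensus_length
        return [
            (r.sequence_id, "".join(r.residue_at(k) for k in range(1, m + 1)))
            for r in recs
        ]

    # -- refinement ----------------------------------------------------------

    def refine(
        self,
        seeds: list[tuple[str, str]],
        cycles: int = 3,
        score_floor: float = 0.0,
    ) -> "ProfileModel":
        """Realign seeds to the current model and rebuild, ``cycles`` times.

        Seeds whose bit score drops below ``score_floor`` are dropped with a
        warning.  Returns the model from the final cycle.
        """
        if cycles < 1:
            raise ValueError("cycles must be >= 1")
        model = self
        kept = list(seeds)
        for cycle in range(cycles):
            scores = model.score_sequences(kept)
            dropped = [sid for sid, _ in kept if scores[str(sid)] < score_floor]
            if dropped:
                log.warning("refine cycle %d: dropping seeds %s", cycle + 1, dropped)
                kept = [(sid, s) for sid, s in kept if str(sid) not in set(dropped)]
            if len(kept) < 2:
                raise ValueError("fewer than 2 seeds survive refinement")
            msa = pyhmmer.hmmer.hmmalign(model.hmm, _digitize(kept), trim=False)
            aligned = [
                (_as_str(name), row.replace(".", "-").upper())
                for name, row in zip(msa.names, msa.alignment)
            ]
            model = ProfileModel.from_alignment(aligned, name=self._name())
            model.seed_ids = [sid for sid, _ in kept]
            model.refine_cycles = cycle + 1
        return model

    # -- persistence ---------------------------------------------------------

    def _name(self) -> str:
        return _as_str(self.hmm.name or "profile")

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "wb") as fh:
            self.hmm.write(fh, binary=False)
        formats.write_json(
            {"seed_ids": self.seed_ids, "refine_cycles": self.refine_cycles,
             "format": "hmmer3-text", "version": 1},
            path.with_suffix(path.suffix + ".json"),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ProfileModel":
        path = Path(path)
        with HMMFile(str(path)) as fh:
            hmm = fh.read()
        meta_path = path.with_suffix(path.suffix + ".json")
        meta = formats.read_json(meta_path) if meta_path.exists() else {}
        return cls(
            hmm=hmm,
            seed_ids=list(meta.get("seed_ids", [])),
            refine_cycles=int(meta.get("refine_cycles", 0)),
        )


def build_profile(seed_alignment: list[tuple[str, str]], name: str = "profile") -> ProfileModel:
    """Functional alias for :meth:`ProfileModel.from_alignment`."""
    return ProfileModel.from_alignment(seed_alignment, name=name)


def refine_profile(
    model: ProfileModel, seeds: list[tuple[str, str]], cycles: int = 3
) -> ProfileModel:
    return model.refine(seeds, cycles=cycles)


# ---------------------------------------------------------------------------
# Codon-aware back-translation


def backtranslate_alignment(
    protein_alignment: list[tuple[str, str]],
    nt_sequences: dict[str, str],
    genetic_code: int = formats.DEFAULT_GENETIC_CODE,
) -> list[tuple[str, str]]:
    """Expand a protein alignment to a codon alignment of the underlying genes.

    Every protein gap becomes a 3-nt gap; ungapped columns are intact codons;
    removing gaps recovers the input nucleotide sequence exactly.  Each
    nucleotide sequence must translate (frame 0) to its ungapped protein,
    optionally carrying a trailing stop codon which is dropped.
    """
    out = []
    for sid, row in protein_alignment:
        nt = nt_sequences[sid]
        protein = row.replace("-", "").replace(".", "")
        core = nt
        if len(core) == 3 * len(protein) + 3:
            trans = formats.translate(core, genetic_code)
            if trans.endswith("*"):
                core = core[:-3]
        if len(core) != 3 * len(protein):
            raise ValueError(
                f"{sid}: nucleotide length {len(core)} does not match "
                f"3 x protein length {3 * len(protein)}"
            )
        trans = formats.translate(core, genetic_code)
        mism = sum(1 for a, b in zip(trans, protein.upper()) if a != b and "X" not in (a, b))
        if mism:
            raise ValueError(f"{sid}: nucleotide sequence does not translate to protein")
        codons = [core[i : i + 3] for i in range(0, len(core), 3)]
        pieces = []
        k = 0
        for c in row:
            if c in "-.":
                pieces.append("---")
            else:
                pieces.append(codons[k])
                k += 1
        out.append((sid, "".join(pieces)))
    return out
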