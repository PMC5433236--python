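"""Frameshift-aware translated alignment of nucleotide reads to proteins.

Coding amplicons sequenced on short-read platforms carry occasional 1–2 nt
indels that knock the read out of frame.  This module aligns a nucleotide
read locally against a protein reference with a dynamic program whose
emission columns consume either a full codon (scored by a substitution
matrix against the reference residue) or a frameshifted 2-nt / 4-nt codon
(fixed penalty), plus affine protein-level gaps.  The traceback is used to
repair the read: 2-nt columns are padded and 4-nt columns trimmed to the
codon best matching the aligned reference residue, restoring the frame.

Scoring defaults (BLOSUM62, gap open/extend -11/-1, frameshift -12 per
event) follow common defaults of frameshift-correcting amplicon tools.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap(args[0]) if args and callable(args[0]) else wrap


NEG = -1e30

_BLOSUM = substitution_matrices.load("BLOSUM62")
_MATRIX_ALPHABET = str(_BLOSUM.alphabet)  # includes B, Z, X and '*'
_AA_INDEX = {a: i for i, a in enumerate(_MATRIX_ALPHABET)}
_MATRIX = np.array(_BLOSUM, dtype=np.float64)

_NT_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _codon_tables(genetic_code: int = 11) -> np.ndarray:
    """Map codon index (16*a+4*b+c, base 4; 64 = ambiguous) -> matrix aa index."""
    table = CodonTable.unambiguous_dna_by_id[genetic_code]
    out = np.full(65, _AA_INDEX["X"], dtype=np.int64)
    for c0, c1, c2 in itertools.product("ACGT", repeat=3):
        codon = c0 + c1 + c2
        idx = 16 * _NT_INDEX[c0] + 4 * _NT_INDEX[c1] + _NT_INDEX[c2]
        if codon in table.stop_codons:
            out[idx] = _AA_INDEX["*"]
        else:
            out[idx] = _AA_INDEX[table.forward_table[codon]]
    return out


_CODON_TO_AA = _codon_tables(11)
_AA_FROM_INDEX = {i: a for a, i in _AA_INDEX.items()}


def encode_nt(nt: str) -> np.ndarray:
    return np.array([_NT_INDEX.get(c, 4) for c in nt.upper()], dtype=np.int64)


def encode_protein(protein: str) -> np.ndarray:
    x = _AA_INDEX["X"]
    return np.array([_AA_INDEX.get(c, x) for c in protein.upper()], dtype=np.int64)


def codon_index(nt_codes: np.ndarray, i: int) -> int:
    a, b, c = nt_codes[i], nt_codes[i + 1], nt_codes[i + 2]
    if a > 3 or b > 3 or c > 3:
        return 64
    return int(16 * a + 4 * b + c)


def translate_codes(nt_codes: np.ndarray, genetic_code_map: np.ndarray = _CODON_TO_AA) -> str:
    n = len(nt_codes) - len(nt_codes) % 3
    return "".join(
        _AA_FROM_INDEX[int(genetic_code_map[codon_index(nt_codes, i)])]
        for i in range(0, n, 3)
    )


@dataclass
class FrameshiftParams:
    gap_open: float = -11.0
    gap_extend: float = -1.0
    frameshift: float = -12.0
    genetic_code: int = 11

    def codon_to_aa(self) -> np.ndarray:
        if self.genetic_code == 11:
            return _CODON_TO_AA
        return _codon_tables(self.genetic_code)


@njit(cache=True)
def _fill(nt, ref, matrix, codon_to_aa, gap_open, gap_extend, fs_pen):  # pragma: no cover - numba
    # Global in the read, local in the reference: the whole read is
    # consumed (a corrector must return the entire corrected read), while
    # the alignment may start and end anywhere on the reference.
    n = nt.shape[0]
    m = ref.shape[0]
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    H = np.full((n + 1, m + 1), NEG)
    for j in range(m + 1):
        H[0, j] = 0.0  # free start anywhere on the reference
    for i in range(1, n + 1):
        for j in range(m + 1):
            if j >= 1:
                best = NEG
                # full codon emission
                if i >= 3:
                    a, b, c = nt[i - 3], nt[i - 2], nt[i - 1]
                    ci = 64 if (a > 3 or b > 3 or c > 3) else 16 * a + 4 * b + c
                    s = H[i - 3, j - 1] + matrix[codon_to_aa[ci], ref[j - 1]]
                    if s > best:
                        best = s
                # 2-nt frameshift column
                if i >= 2:
                    s = H[i - 2, j - 1] + fs_pen
                    if s > best:
                        best = s
                # 4-nt frameshift column
                if i >= 4:
                    s = H[i - 4, j - 1] + fs_pen
                    if s > best:
                        best = s
                M[i, j] = best
            # codon insertion in the read (gap in reference)
            if i >= 3:
                o = H[i - 3, j] + gap_open
                e = X[i - 3, j] + gap_extend
                X[i, j] = o if o > e else e
            # reference residue deleted from the read
            if j >= 1:
                o = H[i, j - 1] + gap_open
                e = Y[i, j - 1] + gap_extend
                Y[i, j] = o if o > e else e
            h = M[i, j]
            if X[i, j] > h:
                h = X[i, j]
            if Y[i, j] > h:
                h = Y[i, j]
            H[i, j] = h
    return M, X, Y, H


@dataclass
class AlignmentColumn:
    op: str        # "M" codon | "F2" | "F4" | "X" insertion | "Y" deletion
    read_start: int
    read_end: int
    ref_pos: int   # 0-based reference position, -1 for insertions


@dataclass
class FsAlignment:
    score: float
    columns: list[AlignmentColumn] = field(default_factory=list)
    read_start: int = 0
    read_end: int = 0
    ref_start: int = 0
    ref_end: int = 0

    @property
    def frameshift_count(self) -> int:
        return sum(1 for c in self.columns if c.op in ("F2", "F4"))


def align_read(
    read_nt: str, ref_protein: str, params: FrameshiftParams | None = None
) -> FsAlignment:
    """Best frameshift-aware alignment of a read to one reference.

    The alignment is global in the read and local in the reference; the
    returned score may be <= 0 for reads unrelated to the reference, which
    callers treat as a failed alignment.
    """
    params = params or FrameshiftParams()
    if len(read_nt) < 3:
        raise ValueError("read shorter than one codon")
    nt = encode_nt(read_nt)
    ref = encode_protein(ref_protein)
    if len(ref) == 0:
        return FsAlignment(score=NEG)
    c2a = params.codon_to_aa()
    M, X, Y, H = _fill(
        nt, ref, _MATRIX, c2a, params.gap_open, params.gap_extend, params.frameshift
    )
    n = len(nt)
    # end: all read consumed; trailing reference deletions are pointless
    end_state, end_j = max(
        ((st, j) for st in ("M", "X") for j in range(len(ref) + 1)),
        key=lambda sj: ({"M": M, "X": X}[sj[0]][n, sj[1]], sj[0] == "M", -sj[1]),
    )
    score = float({"M": M, "X": X}[end_state][n, end_j])
    if not np.isfinite(score) or score <= NEG / 2:
        return FsAlignment(score=NEG)
    cols: list[AlignmentColumn] = []
    i, j, state = n, end_j, end_state
    end_i = n

    def _h_state(i: int, j: int) -> str | None:
        if i == 0:
            return None  # start of the read
        if H[i, j] == M[i, j]:
            return "M"
        if H[i, j] == X[i, j]:
            return "X"
        return "Y"

    while i > 0 or state == "Y":
        if state == "M":
            prev = None
            if i >= 3:
                ci = codon_index(nt, i - 3)
                s = H[i - 3, j - 1] + _MATRIX[c2a[ci], ref[j - 1]]
                if s == M[i, j]:
                    prev = ("M", 3)
            if prev is None and i >= 2 and H[i - 2, j - 1] + params.frameshift == M[i, j]:
                prev = ("F2", 2)
            if prev is None and i >= 4 and H[i - 4, j - 1] + params.frameshift == M[i, j]:
                prev = ("F4", 4)
            assert prev is not None, "traceback failed"
            op, width = prev
            cols.append(AlignmentColumn(op, i - width, i, j - 1))
            i, j = i - width, j - 1
            nxt = _h_state(i, j)
            if nxt is None:
                break
            state = nxt
        elif state == "X":
            cols.append(AlignmentColumn("X", i - 3, i, -1))
            came_extend = X[i - 3, j] + params.gap_extend == X[i, j]
            i -= 3
            if came_extend and np.isfinite(X[i, j]):
                state = "X"
            else:
                nxt = _h_state(i, j)
                if nxt is None:
                    break
                state = nxt
        else:  # Y
            cols.append(AlignmentColumn("Y", i, i, j - 1))
            came_extend = Y[i, j - 1] + params.gap_extend == Y[i, j]
            j -= 1
            if came_extend and np.isfinite(Y[i, j]):
                state = "Y"
            else:
                nxt = _h_state(i, j)
                if nxt is None:
                    break
                state = nxt
    cols.reverse()
    return FsAlignment(
        score=score,
        columns=cols,
        read_start=0,
        read_end=end_i,
        ref_start=j,
        ref_end=end_j,
    )


def _best_completion(bases: str, ref_aa: str, c2a: np.ndarray, pad: bool) -> str:
    """Choose the in-frame codon repairing a frameshifted column.

    ``pad``: insert one base into 2 observed nt (12 candidates); otherwise
    drop one of 4 observed nt (4 candidates).  The codon translating to the
    residue scoring best against the aligned reference residue wins; ties go
    to the lexicographically smallest codon.
    """
    ref_idx = _AA_INDEX.get(ref_aa.upper(), _AA_INDEX["X"])
    candidates = set()
    if pad:
        for pos in range(3):
            for b in "ACGT":
                candidates.add(bases[:pos] + b + bases[pos:])
    else:
        for pos in range(4):
            candidates.add(bases[:pos] + bases[pos + 1:])
    def key(codon: str):
        codes = encode_nt(codon)
        aa = int(c2a[codon_index(codes, 0)])
        return (-_MATRIX[aa, ref_idx], codon)
    return min(candidates, key=key)


@dataclass
class CorrectionResult:
    corrected_nt: str
    corrected_protein: str
    aligned_ref: str       # reference residues over alignment columns ('-' at X)
    aligned_read: str      # corrected residues over alignment columns ('-' at Y)
    identity: float
    frameshift_count: int
    has_stop: bool
    score: float
    alignment: FsAlignment
    ref_positions: list[int] = None  # per corrected codon: 0-based ref residue, -1 for insertions


def correct_read(
    read_nt: str, ref_protein: str, params: FrameshiftParams | None = None
) -> CorrectionResult:
    """Align and frame-repair a read against one protein reference.

    Identity is matches over all alignment columns (gap columns count in the
    denominator; there are no gap-gap columns in a pairwise alignment).
    """
    params = params or FrameshiftParams()
    aln = align_read(read_nt, ref_protein, params)
    c2a = params.codon_to_aa()
    read = read_nt.upper()
    codons: list[str] = []
    read_col: list[str] = []
    ref_col: list[str] = []
    ref_positions: list[int] = []
    for col in aln.columns:
        piece = read[col.read_start : col.read_end]
        if col.op == "M":
            codons.append(piece)
            aa = _AA_FROM_INDEX[int(c2a[codon_index(encode_nt(piece), 0)])]
            read_col.append(aa)
            ref_col.append(ref_protein[col.ref_pos])
            ref_positions.append(col.ref_pos)
        elif col.op == "F2":
            fixed = _best_completion(piece, ref_protein[col.ref_pos], c2a, pad=True)
            codons.append(fixed)
            read_col.append(_AA_FROM_INDEX[int(c2a[codon_index(encode_nt(fixed), 0)])])
            ref_col.append(ref_protein[col.ref_pos])
            ref_positions.append(col.ref_pos)
        elif col.op == "F4":
            fixed = _best_completion(piece, ref_protein[col.ref_pos], c2a, pad=False)
            codons.append(fixed)
            read_col.append(_AA_FROM_INDEX[int(c2a[codon_index(encode_nt(fixed), 0)])])
            ref_col.append(ref_protein[col.ref_pos])
            ref_positions.append(col.ref_pos)
        elif col.op == "X":
            codons.append(piece)
            aa = _AA_FROM_INDEX[int(c2a[codon_index(encode_nt(piece), 0)])]
            read_col.append(aa)
            ref_col.append("-")
            ref_positions.append(-1)
        else:  # Y
            read_col.append("-")
            ref_col.append(ref_protein[col.ref_pos])
    corrected_nt = "".join(codons)
    corrected_protein = "".join(c for c in read_col if c != "-")
    ncols = len(read_col)
    matches = sum(1 for a, b in zip(read_col, ref_col) if a == b and a != "-")
    identity = matches / ncols if ncols else 0.0
    return CorrectionResult(
        corrected_nt=corrected_nt,
        corrected_protein=corrected_protein,
        aligned_ref="".join(ref_col),
        aligned_read="".join(read_col),
        identity=identity,
        frameshift_count=aln.frameshift_count,
        has_stop="*" in corrected_protein,
        score=aln.score,
        alignment=aln,
        ref_positions=ref_positions,
    )
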