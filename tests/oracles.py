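"""Independent reference implementations used to validate the package.

Written deliberately in a different style from the production code (plain
recursion with memoisation, Biopython translation, exhaustive candidate
enumeration) so that agreement is meaningful.  All scores are integer-valued
in float64, so score equality is exact.
"""

from functools import lru_cache
from itertools import product

from Bio.Align import substitution_matrices
from Bio.Seq import Seq

BLOSUM = substitution_matrices.load("BLOSUM62")


def aa_of(codon: str) -> str:
    if len(codon) != 3 or any(c not in "ACGT" for c in codon):
        return "X"
    return str(Seq(codon).translate(table=11))


def blosum(a: str, b: str) -> float:
    a = a if a in BLOSUM.alphabet else "X"
    b = b if b in BLOSUM.alphabet else "X"
    return float(BLOSUM[a][b])


def oracle_align(read: str, ref: str, go=-11.0, ge=-1.0, fs=-12.0):
    """Best score of a read-global / reference-local frameshift-aware
    alignment, by memoised recursion over (nt consumed, ref consumed, state).
    """
    read = read.upper()
    n, m = len(read), len(ref)

    @lru_cache(maxsize=None)
    def best(i, j, state):
        # best score of an alignment consuming read[:i] and ending at ref
        # position j in the given state
        if state == "M":
            if j == 0:
                return None
            cands = []
            if i >= 3:
                h = H(i - 3, j - 1)
                if h is not None:
                    cands.append(h + blosum(aa_of(read[i - 3 : i]), ref[j - 1]))
            if i >= 2:
                h = H(i - 2, j - 1)
                if h is not None:
                    cands.append(h + fs)
            if i >= 4:
                h = H(i - 4, j - 1)
                if h is not None:
                    cands.append(h + fs)
            return max(cands) if cands else None
        if state == "X":
            if i < 3:
                return None
            cands = []
            h = H(i - 3, j)
            if h is not None:
                cands.append(h + go)
            x = best(i - 3, j, "X")
            if x is not None:
                cands.append(x + ge)
            return max(cands) if cands else None
        # Y
        if j == 0:
            return None
        cands = []
        h = H(i, j - 1)
        if h is not None:
            cands.append(h + go)
        y = best(i, j - 1, "Y")
        if y is not None:
            cands.append(y + ge)
        return max(cands) if cands else None

    def H(i, j):
        if i == 0:
            return 0.0
        vals = [v for v in (best(i, j, s) for s in "MXY") if v is not None]
        return max(vals) if vals else None

    ends = [v for j in range(m + 1) for v in (best(n, j, "M"), best(n, j, "X")) if v is not None]
    return max(ends) if ends else None


def oracle_repair_f2(dinuc: str, ref_aa: str) -> str:
    """All codons containing the two observed bases in order; best vs ref."""
    cands = {
        c0 + c1 + c2
        for c0, c1, c2 in product("ACGT", repeat=3)
        if any(
            (c0 + c1 + c2)[:p] + (c0 + c1 + c2)[p + 1 :] == dinuc for p in range(3)
        )
    }
    return min(cands, key=lambda c: (-blosum(aa_of(c), ref_aa), c))


def oracle_repair_f4(quad: str, ref_aa: str) -> str:
    cands = {quad[:p] + quad[p + 1 :] for p in range(4)}
    return min(cands, key=lambda c: (-blosum(aa_of(c), ref_aa), c))


def oracle_complete_linkage(ids, dist, cutoff):
    """Naive agglomerative complete linkage, recomputing the max pairwise
    distance from scratch at every step."""
    t = 1.0 - cutoff + 1e-12
    idx = {sid: k for k, sid in enumerate(ids)}
    clusters = [[sid] for sid in ids]

    def linkdist(a, b):
        return max(dist[idx[x], idx[y]] for x in a for y in b)

    while True:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = linkdist(clusters[i], clusters[j])
                if d > t:
                    continue
                key = (d, tuple(sorted([min(clusters[i]), min(clusters[j])])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        if best is None:
            break
        _, i, j = best
        merged = sorted(clusters[i] + clusters[j])
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return sorted([sorted(c) for c in clusters], key=lambda c: c[0])
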