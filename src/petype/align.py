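"""Global pairwise alignment, percent identity, and a simple progressive MSA.

The aligner is a Needleman-Wunsch / Gotoh implementation with affine gap
costs, end gaps penalized, and a fixed traceback tie-break (diagonal > up >
left, and within a cell match-state > gap-in-a > gap-in-b) so that results
are bit-reproducible. A gap of length L costs ``gap_open + L * gap_extend``.

The progressive MSA follows the classic recipe: pairwise identity distances,
a UPGMA guide tree, then profile-profile Needleman-Wunsch merges in guide-
tree order. Gaps, once inserted, are never removed. This is deliberately a
simple deterministic scheme; precomputed alignments from consistency-based
aligners can be imported through :func:`petype.seqio.read_msa_fasta` when
fidelity to a published MSA matters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .seqio import GAP, Msa, ProteinSequence

NEG_INF = float("-inf")

try:  # the Gotoh DP is compiled when numba is available (it is in standard envs)
    from numba import njit
except ImportError:  # pragma: no cover - fallback for minimal installs
    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


class AlignError(ValueError):
    pass


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric residue substitution score table."""

    alphabet: str
    scores: dict[tuple[str, str], float]

    def score(self, a: str, b: str) -> float:
        return self.scores[(a, b)]

    @classmethod
    def blosum62(cls) -> "SubstitutionMatrix":
        m = substitution_matrices.load("BLOSUM62")
        alphabet = "".join(c for c in m.alphabet if c in "ACDEFGHIKLMNPQRSTVWYX")
        scores: dict[tuple[str, str], float] = {}
        for a in alphabet:
            for b in alphabet:
                scores[(a, b)] = float(m[a, b])
        return cls(alphabet=alphabet, scores=scores)

    @classmethod
    def from_ncbi_file(cls, path) -> "SubstitutionMatrix":
        """Read an NCBI-format matrix text file (rows/cols of scores)."""
        with open(path) as fh:
            lines = [ln for ln in fh if not ln.startswith("#") and ln.strip()]
        cols = lines[0].split()
        scores: dict[tuple[str, str], float] = {}
        letters = []
        for ln in lines[1:]:
            parts = ln.split()
            row = parts[0]
            letters.append(row)
            for c, v in zip(cols, parts[1:]):
                scores[(row, c)] = float(v)
        alphabet = "".join(c for c in letters if len(c) == 1)
        return cls(alphabet=alphabet, scores=scores)


_DEFAULT_MATRIX: SubstitutionMatrix | None = None


def default_matrix() -> SubstitutionMatrix:
    global _DEFAULT_MATRIX
    if _DEFAULT_MATRIX is None:
        _DEFAULT_MATRIX = SubstitutionMatrix.blosum62()
    return _DEFAULT_MATRIX


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    match_count: int
    aligned_columns: int

    @property
    def identity_pct(self) -> float:
        if self.aligned_columns == 0:
            raise AlignError("identity undefined for an empty alignment")
        return 100.0 * self.match_count / self.aligned_columns


def _score_lookup(matrix: SubstitutionMatrix) -> tuple[np.ndarray, dict[str, int]]:
    idx = {c: i for i, c in enumerate(matrix.alphabet)}
    n = len(matrix.alphabet)
    tab = np.zeros((n, n))
    for (a, b), v in matrix.scores.items():
        if a in idx and b in idx:
            tab[idx[a], idx[b]] = v
    return tab, idx


# traceback pointer codes
_DIAG, _UP, _LEFT = 0, 1, 2


@njit(cache=True)
def _gotoh_fill(ia, ib, tab, go, ge):  # pragma: no cover - exercised via global_align
    n, m = len(ia), len(ib)
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    ptrM = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrX = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(go + ge * i)
        ptrX[i, 0] = 1
    for j in range(1, m + 1):
        Y[0, j] = -(go + ge * j)
        ptrY[0, j] = 2
    if n >= 1:
        ptrX[1, 0] = 0
    if m >= 1:
        ptrY[0, 1] = 0
    for i in range(1, n + 1):
        ai = ia[i - 1]
        for j in range(1, m + 1):
            s = tab[ai, ib[j - 1]]
            # M layer: prefer M > X > Y on ties
            best = M[i - 1, j - 1]
            k = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                k = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                k = 2
            M[i, j] = best + s
            ptrM[i, j] = k
            # X layer (gap in b): open from M/Y or extend X
            src = M[i - 1, j] if M[i - 1, j] >= Y[i - 1, j] else Y[i - 1, j]
            open_x = src - (go + ge)
            ext_x = X[i - 1, j] - ge
            if open_x >= ext_x:
                X[i, j] = open_x
                ptrX[i, j] = 0 if M[i - 1, j] >= Y[i - 1, j] else 2
            else:
                X[i, j] = ext_x
                ptrX[i, j] = 1
            # Y layer (gap in a)
            src = M[i, j - 1] if M[i, j - 1] >= X[i, j - 1] else X[i, j - 1]
            open_y = src - (go + ge)
            ext_y = Y[i, j - 1] - ge
            if open_y >= ext_y:
                Y[i, j] = open_y
                ptrY[i, j] = 0 if M[i, j - 1] >= X[i, j - 1] else 1
            else:
                Y[i, j] = ext_y
                ptrY[i, j] = 2
    return M, X, Y, ptrM, ptrX, ptrY


def global_align(
    a: ProteinSequence | str,
    b: ProteinSequence | str,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> AlignmentResult:
    """Optimal global alignment under affine gap costs, deterministic traceback.

    End gaps are penalized. Ties are broken diagonal > up (gap in ``b``) >
    left (gap in ``a``); among the three state layers the match layer wins.
    """
    sa = a.residues if isinstance(a, ProteinSequence) else a
    sb = b.residues if isinstance(b, ProteinSequence) else b
    if not sa or not sb:
        raise AlignError("cannot align an empty sequence")
    matrix = matrix or default_matrix()
    tab, idx = _score_lookup(matrix)
    try:
        ia = np.array([idx[c] for c in sa])
        ib = np.array([idx[c] for c in sb])
    except KeyError as e:
        raise AlignError(f"residue {e} not covered by the substitution matrix") from e

    n, m = len(sa), len(sb)
    # Three layers: M (diag), X (gap in b / consume a, "up"), Y (gap in a, "left");
    # pointer arrays record which layer each optimum came from (0=M,1=X,2=Y).
    M, X, Y, ptrM, ptrX, ptrY = _gotoh_fill(
        ia, ib, tab, float(gap_open), float(gap_extend)
    )
    finals = (M[n, m], X[n, m], Y[n, m])
    layer = int(np.argmax(finals))
    score = finals[layer]

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if layer == 0:
            prev = ptrM[i, j]
            out_a.append(sa[i - 1])
            out_b.append(sb[j - 1])
            i -= 1
            j -= 1
            layer = int(prev)
        elif layer == 1:
            prev = ptrX[i, j]
            out_a.append(sa[i - 1])
            out_b.append(GAP)
            i -= 1
            layer = int(prev)
        else:
            prev = ptrY[i, j]
            out_a.append(GAP)
            out_b.append(sb[j - 1])
            j -= 1
            layer = int(prev)
    al_a = "".join(reversed(out_a))
    al_b = "".join(reversed(out_b))
    matches = sum(1 for x, y in zip(al_a, al_b) if x == y and x != GAP)
    return AlignmentResult(
        aligned_a=al_a,
        aligned_b=al_b,
        score=float(score),
        match_count=matches,
        aligned_columns=len(al_a),
    )


def percent_identity(res: AlignmentResult) -> float:
    """Identity as matches over aligned columns (any column with >=1 residue), x100.

    Reported to 0.1; note conventions differ (some tools divide by the
    shorter sequence length) so cross-tool comparisons carry a point or two
    of slack.
    """
    return round(res.identity_pct, 1)


# ---------------------------------------------------------------------------
# progressive MSA
# ---------------------------------------------------------------------------


def _profile_columns(rows: list[tuple[str, str]]) -> list[str]:
    return ["".join(s[i] for _, s in rows) for i in range(len(rows[0][1]))]


def _profile_profile_align(
    rows_a: list[tuple[str, str]],
    rows_b: list[tuple[str, str]],
    tab: np.ndarray,
    idx: dict[str, int],
    gap_open: float,
    gap_extend: float,
) -> list[tuple[str, str]]:
    """Needleman-Wunsch on column profiles with sum-of-pairs scores, linear gaps.

    Linear gap cost (open+extend per gap column) keeps profile merging simple;
    pairwise affine alignment is still used for identities and feature maps.
    """
    cols_a = _profile_columns(rows_a)
    cols_b = _profile_columns(rows_b)
    gap_cost = gap_open / 4.0 + gap_extend  # per-column, softened for profiles

    freq_a = _col_freqs(cols_a, idx)
    freq_b = _col_freqs(cols_b, idx)
    n, m = len(cols_a), len(cols_b)
    S = np.einsum("ik,jl,kl->ij", freq_a, freq_b, tab) if n and m else np.zeros((n, m))

    D = np.zeros((n + 1, m + 1))
    P = np.zeros((n + 1, m + 1), dtype=np.int8)
    for i in range(1, n + 1):
        D[i, 0] = -gap_cost * i
        P[i, 0] = _UP
    for j in range(1, m + 1):
        D[0, j] = -gap_cost * j
        P[0, j] = _LEFT
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cands = (
                D[i - 1, j - 1] + S[i - 1, j - 1],
                D[i - 1, j] - gap_cost,
                D[i, j - 1] - gap_cost,
            )
            k = int(np.argmax(cands))
            D[i, j] = cands[k]
            P[i, j] = k
    # traceback
    path: list[int] = []
    i, j = n, m
    while i > 0 or j > 0:
        k = P[i, j]
        path.append(k)
        if k == _DIAG:
            i -= 1
            j -= 1
        elif k == _UP:
            i -= 1
        else:
            j -= 1
    path.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    i = j = 0
    for k in path:
        if k == _DIAG:
            for r, (_, s) in enumerate(rows_a):
                out_a[r] += s[i]
            for r, (_, s) in enumerate(rows_b):
                out_b[r] += s[j]
            i += 1
            j += 1
        elif k == _UP:
            for r, (_, s) in enumerate(rows_a):
                out_a[r] += s[i]
            for r in range(len(rows_b)):
                out_b[r] += GAP
            i += 1
        else:
            for r in range(len(rows_a)):
                out_a[r] += GAP
            for r, (_, s) in enumerate(rows_b):
                out_b[r] += s[j]
            j += 1
    merged = [(rid, out_a[r]) for r, (rid, _) in enumerate(rows_a)]
    merged += [(rid, out_b[r]) for r, (rid, _) in enumerate(rows_b)]
    return merged


def _col_freqs(cols: list[str], idx: dict[str, int]) -> np.ndarray:
    """Per-column residue frequency vectors; gaps contribute zero weight."""
    n_letters = len(idx)
    out = np.zeros((len(cols), n_letters))
    for i, col in enumerate(cols):
        residues = [c for c in col if c != GAP]
        for c in residues:
            out[i, idx[c]] += 1.0
        if residues:
            out[i] /= len(col)  # gap columns weigh less, as in standard profiles
    return out


def progressive_msa(
    seqs: list[ProteinSequence],
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> Msa:
    """Progressive multiple alignment over a UPGMA guide tree."""
    if len(seqs) < 2:
        raise AlignError("progressive MSA needs at least 2 sequences")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise AlignError("duplicate sequence ids in MSA input")
    matrix = matrix or default_matrix()
    tab, idx = _score_lookup(matrix)

    n = len(seqs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = global_align(seqs[i], seqs[j], matrix, gap_open, gap_extend)
            d = 1.0 - res.match_count / res.aligned_columns
            dist[i, j] = dist[j, i] = d
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")

    clusters: dict[int, list[tuple[str, str]]] = {
        i: [(seqs[i].id, seqs[i].residues)] for i in range(n)
    }
    for k, (ci, cj, _, _) in enumerate(linkage):
        merged = _profile_profile_align(
            clusters.pop(int(ci)), clusters.pop(int(cj)), tab, idx, gap_open, gap_extend
        )
        clusters[n + k] = merged
    (rows,) = clusters.values()
    order = {rid: i for i, rid in enumerate(ids)}
    rows.sort(key=lambda r: order[r[0]])
    return Msa(rows=tuple(rows))


def column_frequencies(msa: Msa, columns: range | None = None):
    """Per-column residue frequencies among non-gap rows, plus gap fraction.

    Returns a list of ``(frequencies: dict, gap_fraction: float)``; the
    frequency dict covers residues present in the column and sums to 1.
    This is the table a sequence-logo plot is drawn from.
    """
    if not msa.rows:
        raise AlignError("empty MSA")
    cols = columns if columns is not None else range(msa.column_count)
    out = []
    for i in cols:
        col = msa.column(i)  # raises IndexError when out of range
        residues = [c for c in col if c != GAP]
        freqs: dict[str, float] = {}
        for c in residues:
            freqs[c] = freqs.get(c, 0.0) + 1.0
        if residues:
            for c in freqs:
                freqs[c] /= len(residues)
        out.append((freqs, (len(col) - len(residues)) / len(col)))
    return out
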