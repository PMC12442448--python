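"""A small profile hidden Markov model for homolog mining.

Built from a seed alignment of characterized PET hydrolases, the model
scores candidate sequences as log2-odds ("bit") scores against an i.i.d.
background, which is how the mining thresholds are expressed: a candidate
is a hit when its bit score exceeds 100, and hits split into a low (<200)
and a high (>=200) bit-score group that track the two phylogenetic
sub-clades of the family.

Architecture: nodes 0..k where node 0 is Begin; each node j has a match
state M_j (emitting, j>=1), an insert state I_j and a delete state D_j
(silent, j>=1). Every state at node j transitions to {M_{j+1}, I_j,
D_{j+1}}; at the final node the delete successor does not exist and the
mass is renormalized over {End, I_k}. Alignment mode is glocal (global in
the model). Estimation uses Laplace (+1 by default) pseudocounts rather
than Dirichlet mixtures, so bit scores are on this model's own scale and
are not claimed to be numerically exchangeable with other profile-HMM
software; the 100/200 thresholds are interpreted on whichever score scale
produced them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .seqio import AMINO_ACIDS, GAP, Msa, ProteinSequence

try:
    from numba import njit
except ImportError:  # pragma: no cover - fallback for minimal installs
    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]

LOG0 = float("-inf")
_AA_INDEX = {c: i for i, c in enumerate(AMINO_ACIDS)}
N_AA = len(AMINO_ACIDS)

M, I, D = 0, 1, 2  # successor order within a node's transition vector


class HmmError(ValueError):
    pass


class DegenerateModelError(HmmError):
    pass


@dataclass(frozen=True)
class ProfileHmm:
    """Match/insert/delete profile HMM with log-ready probability tables.

    match_emissions: (k+1, 20), row 0 unused (Begin emits nothing).
    insert_emissions: (k+1, 20), rows 0..k.
    transitions: (3, k+1, 3) indexed [from_state, node, to_state] with
    successor order (M, I, D); at node k the D column is zero.
    null_model: (20,) background residue probabilities.
    """

    match_count: int
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    transitions: np.ndarray
    null_model: np.ndarray

    def validate(self, tol: float = 1e-9) -> None:
        k = self.match_count
        assert abs(self.null_model.sum() - 1) < tol
        for j in range(1, k + 1):
            assert abs(self.match_emissions[j].sum() - 1) < tol
        for j in range(k + 1):
            assert abs(self.insert_emissions[j].sum() - 1) < tol
        for st in (M, I, D):
            for j in range(k + 1):
                if st == D and j == 0:
                    continue
                assert abs(self.transitions[st, j].sum() - 1) < tol


@dataclass(frozen=True)
class HmmScore:
    seq_id: str
    bits: float
    algorithm: str  # "forward" | "viterbi"


def _column_classes(msa: Msa, match_gap_frac: float) -> list[bool]:
    """True where a column is a match column (gap fraction < threshold)."""
    n = len(msa.rows)
    flags = []
    for i in range(msa.column_count):
        gaps = sum(1 for c in msa.column(i) if c == GAP)
        flags.append(gaps / n < match_gap_frac)
    return flags


def build_profile(
    msa: Msa, match_gap_frac: float = 0.5, pseudocount: float = 1.0
) -> ProfileHmm:
    """Estimate a profile HMM from a seed MSA.

    Columns with gap fraction below ``match_gap_frac`` become match states.
    Emissions are (counts + pc) / (total + 20 pc); each state's transition
    vector over its successors is smoothed the same way.
    """
    if len(msa.rows) < 2:
        raise HmmError("seed MSA needs at least 2 rows")
    is_match = _column_classes(msa, match_gap_frac)
    k = sum(is_match)
    if k == 0:
        raise DegenerateModelError("MSA yields zero match columns")

    pc = pseudocount
    m_counts = np.zeros((k + 1, N_AA))
    i_counts = np.zeros((k + 1, N_AA))
    t_counts = np.zeros((3, k + 1, 3))
    null_counts = np.zeros(N_AA)

    for _, row in msa.rows:
        node = 0
        prev = M  # Begin acts as M_0
        for col, ch in enumerate(row):
            if ch != GAP and ch in _AA_INDEX:
                null_counts[_AA_INDEX[ch]] += 1
            if is_match[col]:
                nxt_node = node + 1
                if ch == GAP:
                    t_counts[prev, node, D] += 1
                    prev = D
                else:
                    t_counts[prev, node, M] += 1
                    if ch in _AA_INDEX:
                        m_counts[nxt_node, _AA_INDEX[ch]] += 1
                    prev = M
                node = nxt_node
            else:
                if ch != GAP:
                    t_counts[prev, node, I] += 1
                    if ch in _AA_INDEX:
                        i_counts[node, _AA_INDEX[ch]] += 1
                    prev = I
        # exit: the M successor at node k is End
        t_counts[prev, node, M] += 1

    match_em = (m_counts + pc) / (m_counts.sum(axis=1, keepdims=True) + N_AA * pc)
    insert_em = (i_counts + pc) / (i_counts.sum(axis=1, keepdims=True) + N_AA * pc)
    null = (null_counts + pc) / (null_counts.sum() + N_AA * pc)

    trans = np.zeros((3, k + 1, 3))
    for st in (M, I, D):
        for j in range(k + 1):
            c = t_counts[st, j].copy()
            if j == k:  # no delete successor at the final node
                sub = c[:2] + pc
                trans[st, j, :2] = sub / sub.sum()
            else:
                c = c + pc
                trans[st, j] = c / c.sum()
    return ProfileHmm(
        match_count=k,
        match_emissions=match_em,
        insert_emissions=insert_em,
        transitions=trans,
        null_model=null,
    )


def _encode(seq: ProteinSequence | str) -> np.ndarray:
    s = seq.residues if isinstance(seq, ProteinSequence) else seq
    if not s:
        raise HmmError("cannot score an empty sequence")
    try:
        return np.array([_AA_INDEX[c] for c in s])
    except KeyError as e:
        raise HmmError(f"residue {e} outside the scoring alphabet") from e


def _log2(x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log2(x)


@njit(cache=True)
def _dp_kernel(x, k, lt, lem, lei, viterbi):  # pragma: no cover - via _score
    LOG0 = -1e30
    L = len(x)

    def comb3(a, b, c, vit):
        m = a
        if b > m:
            m = b
        if c > m:
            m = c
        if m <= LOG0 / 2:
            return LOG0
        if vit:
            return m
        s = 2.0 ** (a - m) + 2.0 ** (b - m) + 2.0 ** (c - m)
        return m + np.log2(s)

    fM = np.full((k + 1, L + 1), LOG0)
    fI = np.full((k + 1, L + 1), LOG0)
    fD = np.full((k + 1, L + 1), LOG0)
    fM[0, 0] = 0.0
    for j in range(1, k + 1):
        fD[j, 0] = comb3(
            fM[j - 1, 0] + lt[0, j - 1, 2], LOG0, fD[j - 1, 0] + lt[2, j - 1, 2],
            viterbi,
        )
    for i in range(1, L + 1):
        e0 = lei[0, x[i - 1]]
        fI[0, i] = comb3(
            fM[0, i - 1] + lt[0, 0, 1], fI[0, i - 1] + lt[1, 0, 1], LOG0, viterbi
        ) + e0
        for j in range(1, k + 1):
            em = lem[j, x[i - 1]]
            ei = lei[j, x[i - 1]]
            fM[j, i] = comb3(
                fM[j - 1, i - 1] + lt[0, j - 1, 0],
                fI[j - 1, i - 1] + lt[1, j - 1, 0],
                fD[j - 1, i - 1] + lt[2, j - 1, 0],
                viterbi,
            ) + em
            fI[j, i] = comb3(
                fM[j, i - 1] + lt[0, j, 1],
                fI[j, i - 1] + lt[1, j, 1],
                fD[j, i - 1] + lt[2, j, 1],
                viterbi,
            ) + ei
            fD[j, i] = comb3(
                fM[j - 1, i] + lt[0, j - 1, 2],
                fI[j - 1, i] + lt[1, j - 1, 2],
                fD[j - 1, i] + lt[2, j - 1, 2],
                viterbi,
            )
    return comb3(
        fM[k, L] + lt[0, k, 0], fI[k, L] + lt[1, k, 0], fD[k, L] + lt[2, k, 0],
        viterbi,
    )


def _score(hmm: ProfileHmm, seq: ProteinSequence | str, viterbi: bool) -> float:
    """Glocal forward or Viterbi log2-odds score in bits."""
    x = _encode(seq)
    with np.errstate(divide="ignore"):
        lt = np.where(hmm.transitions > 0, np.log2(np.maximum(hmm.transitions, 1e-300)), -1e30)
        lem = np.where(
            hmm.match_emissions > 0,
            np.log2(np.maximum(hmm.match_emissions, 1e-300)),
            -1e30,
        )
        lei = np.where(
            hmm.insert_emissions > 0,
            np.log2(np.maximum(hmm.insert_emissions, 1e-300)),
            -1e30,
        )
    log_p = _dp_kernel(x, hmm.match_count, lt, lem, lei, viterbi)
    log_null = float(np.log2(hmm.null_model)[x].sum())
    return float(log_p - log_null)


def score_forward(hmm: ProfileHmm, seq: ProteinSequence) -> HmmScore:
    """Forward (summed over all paths) log2-odds score in bits."""
    sid = seq.id if isinstance(seq, ProteinSequence) else "seq"
    return HmmScore(seq_id=sid, bits=_score(hmm, seq, viterbi=False), algorithm="forward")


def score_viterbi(hmm: ProfileHmm, seq: ProteinSequence) -> HmmScore:
    """Best-single-path log2-odds score in bits (never exceeds forward)."""
    sid = seq.id if isinstance(seq, ProteinSequence) else "seq"
    return HmmScore(seq_id=sid, bits=_score(hmm, seq, viterbi=True), algorithm="viterbi")


def filter_and_group(
    scores: list[HmmScore],
    hit_threshold: float = 100.0,
    group_boundary: float = 200.0,
) -> tuple[list[HmmScore], list[HmmScore], list[HmmScore]]:
    """Apply the mining rule: strict bits > hit_threshold; split at the boundary.

    A score exactly at the hit threshold is NOT a hit (the rule is "higher
    than"); a score exactly at the group boundary falls in the high group.
    """
    hits = [s for s in scores if s.bits > hit_threshold]
    low = [s for s in hits if s.bits < group_boundary]
    high = [s for s in hits if s.bits >= group_boundary]
    return hits, low, high


# ---------------------------------------------------------------------------
# plain-text serialization
# ---------------------------------------------------------------------------


def save_profile(hmm: ProfileHmm, path: str | Path) -> None:
    """Write the model as a documented plain-text table."""
    with open(path, "w") as fh:
        fh.write(f"petype-profile-hmm 1\nmatch_states {hmm.match_count}\n")
        fh.write("alphabet " + AMINO_ACIDS + "\n")
        fh.write("null " + " ".join(f"{v:.10g}" for v in hmm.null_model) + "\n")
        for j in range(hmm.match_count + 1):
            fh.write(
                f"node {j} ME "
                + " ".join(f"{v:.10g}" for v in hmm.match_emissions[j])
                + "\n"
            )
            fh.write(
                f"node {j} IE "
                + " ".join(f"{v:.10g}" for v in hmm.insert_emissions[j])
                + "\n"
            )
            for st, lbl in ((M, "TM"), (I, "TI"), (D, "TD")):
                fh.write(
                    f"node {j} {lbl} "
                    + " ".join(f"{v:.10g}" for v in hmm.transitions[st, j])
                    + "\n"
                )


def load_profile(path: str | Path) -> ProfileHmm:
    with open(path) as fh:
        header = fh.readline().split()
        if header[:1] != ["petype-profile-hmm"]:
            raise HmmError(f"{path}: not a petype profile file")
        k = int(fh.readline().split()[1])
        fh.readline()  # alphabet
        null = np.array([float(v) for v in fh.readline().split()[1:]])
        me = np.zeros((k + 1, N_AA))
        ie = np.zeros((k + 1, N_AA))
        tr = np.zeros((3, k + 1, 3))
        lbl_state = {"TM": M, "TI": I, "TD": D}
        for line in fh:
            parts = line.split()
            j, kind, vals = int(parts[1]), parts[2], [float(v) for v in parts[3:]]
            if kind == "ME":
                me[j] = vals
            elif kind == "IE":
                ie[j] = vals
            else:
                tr[lbl_state[kind], j] = vals
    return ProfileHmm(
        match_count=k,
        match_emissions=me,
        insert_emissions=ie,
        transitions=tr,
        null_model=null,
    )


def save_scores_tsv(scores: list[HmmScore], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tbits\talgorithm\n")
        for s in scores:
            fh.write(f"{s.seq_id}\t{s.bits:.4f}\t{s.algorithm}\n")
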