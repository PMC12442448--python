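"""Profile-HMM tests, anchored by an exhaustive path-enumeration oracle.

The oracle enumerates every state path through the model architecture
(nodes 0..k with M/I/D states, glocal) that emits a given sequence and sums
(or maximizes) the path probabilities — fully independent of the log-space
dynamic programming it checks.
"""

import itertools

import numpy as np
import pytest

from petype import synth
from petype.hmm import (
    DegenerateModelError,
    HmmError,
    ProfileHmm,
    build_profile,
    filter_and_group,
    load_profile,
    save_profile,
    score_forward,
    score_viterbi,
    HmmScore,
)
from petype.seqio import AMINO_ACIDS, Msa, ProteinSequence

AA_IDX = {c: i for i, c in enumerate(AMINO_ACIDS)}
M, I, D = 0, 1, 2


def enumerate_paths(hmm: ProfileHmm, length: int):
    """All (path probability, emission-slot list) pairs emitting `length` symbols.

    A path is walked from Begin (M at node 0) until the End transition at the
    final node; emission slots record (state, node) for each emitted symbol.
    """
    k = hmm.match_count
    results = []

    def walk(state, node, emitted, prob):
        if prob == 0.0 or len(emitted) > length:
            return
        trans = hmm.transitions[state, node]
        # to M_{node+1} (or End at node k)
        if node == k:
            if len(emitted) == length:
                results.append((prob * trans[M], list(emitted)))
        else:
            walk(M, node + 1, emitted + [(M, node + 1)], prob * trans[M])
        # to I_node
        walk(I, node, emitted + [(I, node)], prob * trans[I])
        # to D_{node+1}
        if node < k:
            walk(D, node + 1, emitted, prob * trans[D])

    walk(M, 0, [], 1.0)
    return results


def oracle_prob(hmm: ProfileHmm, seq: str, viterbi=False) -> float:
    x = [AA_IDX[c] for c in seq]
    total, best = 0.0, 0.0
    for prob, slots in enumerate_paths(hmm, len(seq)):
        p = prob
        for (state, node), xi in zip(slots, x):
            em = hmm.match_emissions if state == M else hmm.insert_emissions
            p *= em[node, xi]
        total += p
        best = max(best, p)
    return best if viterbi else total


def oracle_bits(hmm: ProfileHmm, seq: str, viterbi=False) -> float:
    null = float(np.prod([hmm.null_model[AA_IDX[c]] for c in seq]))
    return float(np.log2(oracle_prob(hmm, seq, viterbi) / null))


def toy_msa(rows):
    return Msa(rows=tuple((f"s{i}", r) for i, r in enumerate(rows)))


def random_model(rng, k):
    """A random valid model via Dirichlet draws (tests only)."""
    me = rng.dirichlet(np.ones(20), size=k + 1)
    ie = rng.dirichlet(np.ones(20), size=k + 1)
    tr = np.zeros((3, k + 1, 3))
    for st in range(3):
        for j in range(k + 1):
            if j == k:
                tr[st, j, :2] = rng.dirichlet(np.ones(2))
            else:
                tr[st, j] = rng.dirichlet(np.ones(3))
    return ProfileHmm(
        match_count=k,
        match_emissions=me,
        insert_emissions=ie,
        transitions=tr,
        null_model=rng.dirichlet(np.ones(20)),
    )


class TestBuildProfile:
    def test_identical_rows_pseudocount_arithmetic(self):
        hmm = build_profile(toy_msa(["ACD"] * 5))
        assert hmm.match_count == 3
        for j, aa in enumerate("ACD", start=1):
            assert hmm.match_emissions[j, AA_IDX[aa]] == pytest.approx(6 / 25)
        hmm.validate()

    def test_gappy_column_becomes_insert(self):
        rows = ["AD", "AD", "AD", "AD", "AD"]
        gappy = ["A-D", "A-D", "A-D", "ACD", "ACD"]  # middle col gap frac 0.6
        hmm = build_profile(toy_msa(gappy))
        assert hmm.match_count == 2

    def test_normalization_invariant(self, refset):
        from petype.align import progressive_msa

        seqs = list(refset.archetypes.values())[:3]
        build_profile(progressive_msa(seqs)).validate()

    def test_all_gappy_degenerate(self):
        with pytest.raises(DegenerateModelError):
            build_profile(toy_msa(["A--", "-C-", "--D", "---", "---"]))

    def test_single_row_rejected(self):
        with pytest.raises(HmmError):
            build_profile(toy_msa(["ACD"]))


class TestScoring:
    def test_forward_matches_enumeration_on_toy_models(self):
        """Forward bits equal exhaustive path enumeration to 1e-9 bits."""
        for rows, queries in [
            (["A"] * 3, ["A", "C", "G"]),
            (["AC", "AC", "AG"], ["AC", "CA", "A", "ACG"]),
            (["ACD", "ACD", "AVD", "AC-"], ["ACD", "AD", "ACDG"]),
        ]:
            hmm = build_profile(toy_msa(rows))
            for q in queries:
                got = score_forward(hmm, ProteinSequence(id="q", residues=q)).bits
                assert got == pytest.approx(oracle_bits(hmm, q), abs=1e-9), (rows, q)

    def test_viterbi_matches_enumeration_on_toy_models(self):
        hmm = build_profile(toy_msa(["AC", "AC", "AG"]))
        for q in ["AC", "CA", "A", "ACG"]:
            got = score_viterbi(hmm, ProteinSequence(id="q", residues=q)).bits
            assert got == pytest.approx(oracle_bits(hmm, q, viterbi=True), abs=1e-9)

    def test_forward_at_least_viterbi_random_models(self):
        """Sum over paths can never fall below the single best path."""
        rng = np.random.default_rng(42)
        aa = list(AMINO_ACIDS)
        for _ in range(500):
            hmm = random_model(rng, k=int(rng.integers(1, 5)))
            seq = ProteinSequence(
                id="q", residues="".join(rng.choice(aa, size=rng.integers(1, 7)))
            )
            f = score_forward(hmm, seq).bits
            v = score_viterbi(hmm, seq).bits
            assert f >= v - 1e-9

    def test_total_probability_over_sequences_of_fixed_length(self):
        """Summing P(seq) over all two-letter sequences of length L equals the
        model's total probability of emitting length L (path enumeration)."""
        rng = np.random.default_rng(3)
        k = 2
        hmm = random_model(rng, k)
        # restrict emissions to a 2-letter support so the sum is enumerable
        me = np.zeros((k + 1, 20))
        ie = np.zeros((k + 1, 20))
        me[:, AA_IDX["A"]] = 0.6
        me[:, AA_IDX["C"]] = 0.4
        ie[:, AA_IDX["A"]] = 0.3
        ie[:, AA_IDX["C"]] = 0.7
        hmm2 = ProfileHmm(
            match_count=k,
            match_emissions=me,
            insert_emissions=ie,
            transitions=hmm.transitions,
            null_model=hmm.null_model,
        )
        for L in range(1, 5):
            total_len_prob = sum(p for p, _ in enumerate_paths(hmm2, L) if len(_) == L)
            seq_sum = sum(
                oracle_prob(hmm2, "".join(letters))
                for letters in itertools.product("AC", repeat=L)
            )
            assert seq_sum == pytest.approx(total_len_prob, abs=1e-12)

    def test_self_profile_bits_increase_with_length(self):
        """Against a profile of its own copies, a longer sequence scores higher."""
        prev = -np.inf
        for L in (5, 10, 20, 40):
            s = ("ACDEFGHIKL" * 4)[:L]
            hmm = build_profile(toy_msa([s] * 5))
            bits = score_forward(hmm, ProteinSequence(id="q", residues=s)).bits
            assert bits > prev
            prev = bits

    def test_sampled_sequences_outscore_decoys_on_average(self):
        rng_msa = toy_msa(["ACDEFGHIKLMNPQRSTVWY" * 2] * 6)
        hmm = build_profile(rng_msa)
        samples = synth.sample_from_profile(hmm, 100, seed=5)
        mean_len = int(np.mean([len(s.residues) for s in samples]))
        decoys = synth.random_sequences(100, mean_len, seed=6)
        ms = np.mean([score_forward(hmm, s).bits for s in samples])
        md = np.mean([score_forward(hmm, d).bits for d in decoys])
        assert ms > md

    def test_alphabet_error(self):
        hmm = build_profile(toy_msa(["ACD"] * 3))
        with pytest.raises(HmmError):
            score_forward(hmm, ProteinSequence(id="q", residues="AXD"))


class TestFilterAndGroup:
    def test_strict_threshold_and_boundary_membership(self):
        scores = [
            HmmScore("a", 99.9, "forward"),
            HmmScore("b", 100.0, "forward"),
            HmmScore("c", 150.0, "forward"),
            HmmScore("d", 250.0, "forward"),
        ]
        hits, low, high = filter_and_group(scores)
        assert [s.seq_id for s in hits] == ["c", "d"]  # 100.0 excluded: strict >
        assert [s.seq_id for s in low] == ["c"]
        assert [s.seq_id for s in high] == ["d"]

    def test_exact_boundary_goes_high(self):
        hits, low, high = filter_and_group([HmmScore("e", 200.0, "forward")])
        assert [s.seq_id for s in high] == ["e"] and low == []

    def test_empty_input(self):
        assert filter_and_group([]) == ([], [], [])


def test_serialization_round_trip(tmp_path):
    hmm = build_profile(toy_msa(["ACDE", "ACDE", "AC-E", "GCDE"]))
    p = tmp_path / "model.txt"
    save_profile(hmm, p)
    back = load_profile(p)
    q = ProteinSequence(id="q", residues="ACDE")
    assert score_forward(back, q).bits == pytest.approx(score_forward(hmm, q).bits)
    back.validate()
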