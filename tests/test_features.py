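import pytest

from petype import synth
from petype.features import (
    FeatureError,
    check_clamp,
    extended_loop_coverage,
    extract_features,
    extract_lipase_box,
    infer_disulfides_from_sequence,
    map_positions,
    measure_loops,
    read_annotation_tsv,
    write_annotation_tsv,
)
from petype.seqio import ProteinSequence


@pytest.fixture(scope="module")
def ref(refset):
    return refset.archetypes["IIb"]


@pytest.fixture(scope="module")
def ann(refset):
    return refset.annotation


class TestLipaseBox:
    @pytest.mark.parametrize(
        "window,label",
        [("GHSQG", "GHSQG"), ("GWSMG", "GWSMG"), ("GHSMG", "GHSMG"), ("GASTG", "other")],
    )
    def test_motif_variants(self, window, label):
        seq = ProteinSequence(id="q", residues="AAA" + window + "AAA")
        motif, got = extract_lipase_box(seq, ser_pos=6)
        assert motif == window and got == label

    def test_center_not_serine_nonconforming(self):
        seq = ProteinSequence(id="q", residues="AAAGHTQGAAA")
        motif, label = extract_lipase_box(seq, ser_pos=6)
        assert label == "nonconforming"

    def test_window_out_of_range(self):
        seq = ProteinSequence(id="q", residues="GSG")
        with pytest.raises(FeatureError):
            extract_lipase_box(seq, ser_pos=2)


class TestMapPositions:
    def test_reference_maps_to_itself_identically(self, ref):
        pmap = map_positions(ref, ref)
        assert all(pmap.ref_to_query[p] == p for p in range(1, len(ref.residues) + 1))

    def test_round_trip_for_mapped_sites(self, refset, ref):
        q = refset.archetypes["III"]
        pmap = map_positions(q, ref)
        for rp, qp in pmap.ref_to_query.items():
            if qp is not None:
                assert pmap.query_to_ref[qp] == rp

    def test_clamp_anchor_2_maps_to_planted_tyrosine(self, refset, ref, ann):
        """The type III archetype's anchor-2 equivalent is its planted Y."""
        q = refset.archetypes["III"]
        pmap = map_positions(q, ref)
        qpos = pmap.get(ann.clamp_anchor_2)
        assert qpos is not None and q.residue_at(qpos) == "Y"

    def test_deleted_loop_position_is_unalignable(self, refset, ref):
        """The subsite residue on the deleted loop has no equivalent — the map
        must report it unalignable, not force a neighbor."""
        q = refset.archetypes["III"]
        pmap = map_positions(q, ref)
        assert pmap.get(119) is None


class TestClamp:
    def test_broken_clamp_on_type_iii(self, refset, ref, ann):
        q = refset.archetypes["III"]
        present, r1, r2 = check_clamp(q, map_positions(q, ref), ann)
        assert present is False
        assert r1 == "T" and r2 == "Y"

    def test_intact_clamp_on_reference(self, ref, ann):
        present, r1, r2 = check_clamp(ref, map_positions(ref, ref), ann)
        assert present is True and (r1, r2) == ("Y", "W")

    def test_fw_pair_counts_as_clamp(self, ref, ann):
        mutant = ProteinSequence(
            id="mut",
            residues=ref.residues[: ann.clamp_anchor_1 - 1]
            + "F"
            + ref.residues[ann.clamp_anchor_1 :],
        )
        present, r1, r2 = check_clamp(mutant, map_positions(mutant, ref), ann)
        assert present is True and r1 == "F"


class TestLoops:
    def test_reference_against_itself_all_zero(self, ref, ann):
        assert measure_loops(ref, ref, ann) == {1: 0, 2: 0, 3: 0}

    def test_type_iii_loop_signature(self, refset, ref, ann):
        deltas = measure_loops(refset.archetypes["III"], ref, ann)
        assert deltas[3] == +5  # planted five-residue insertion
        assert deltas[2] == -5  # planted five-residue deletion
        assert deltas[1] == 0

    def test_reverse_direction_negates(self, refset, ref, ann):
        import dataclasses

        q = refset.archetypes["III"]
        fwd = measure_loops(q, ref, ann)
        # reverse: windows must be expressed in the query's own numbering
        pmap = map_positions(q, ref)
        rev_windows = {}
        for n, (s, e) in ann.loop_windows.items():
            qs = next(pmap.ref_to_query[p] for p in range(s, e + 1) if pmap.ref_to_query.get(p))
            qe = next(
                pmap.ref_to_query[p] for p in range(e, s - 1, -1) if pmap.ref_to_query.get(p)
            )
            rev_windows[n] = (qs, qe)
        rev_ann = dataclasses.replace(ann, ref_id=q.id, loop_windows=rev_windows)
        rev = measure_loops(ref, q, rev_ann)
        for n in fwd:
            assert rev[n] == -fwd[n]

    def test_extended_loop_coverage_absent_in_type_i(self, refset, ref, ann):
        assert extended_loop_coverage(refset.archetypes["I"], ref, ann) < 0.5
        assert extended_loop_coverage(refset.archetypes["IIa"], ref, ann) >= 0.5


class TestDisulfideInference:
    def test_canonical_pairs_on_type_iib(self, refset, ref, ann):
        pmap = map_positions(ref, ref)
        pairs, unpaired = infer_disulfides_from_sequence(ref, ann, pmap)
        assert [(p, c) for p, c in pairs] == [((203, 239), True), ((273, 289), True)]
        assert unpaired == []

    def test_type_iii_pairs_all_noncanonical(self, refset, ref, ann):
        q = refset.archetypes["III"]
        pairs, _ = infer_disulfides_from_sequence(q, ann, map_positions(q, ref))
        assert [p for p, _ in pairs] == [(64, 126), (273, 276)]
        assert all(not canonical for _, canonical in pairs)

    def test_odd_cysteine_count_leaves_unpaired(self, ref, ann):
        # add a lone extra cysteine far from everything
        res = ref.residues[:29] + "C" + ref.residues[30:]
        q = ProteinSequence(id="odd", residues=res)
        pairs, unpaired = infer_disulfides_from_sequence(q, ann, map_positions(q, ref))
        assert unpaired == [30]
        assert len(pairs) == 2

    def test_structure_bonds_override_sequence(self, refset, ref, ann):
        from petype.structure import DisulfideBond

        q = refset.archetypes["III"]
        bonds = [DisulfideBond(cys_a=64, cys_b=126, sg_distance=2.05)]
        pairs, unpaired = infer_disulfides_from_sequence(
            q, ann, map_positions(q, ref), structure_bonds=bonds
        )
        assert [p for p, _ in pairs] == [(64, 126)]
        assert set(unpaired) == {273, 276}


class TestFullReport:
    def test_type_iii_report_recovers_planted_features(self, refset, ref, ann):
        rep = extract_features(refset.archetypes["III"], ref, ann)
        assert rep.lipase_box == "GHSQG"
        assert rep.clamp_present is False
        assert rep.n_disulfides == 2 and rep.all_noncanonical
        assert rep.extended_loop_present
        assert rep.loop_deltas == {1: 0, 2: -5, 3: +5}
        assert not rep.blocked
        assert not rep.structure_derived

    def test_type_i_report(self, refset, ref, ann):
        rep = extract_features(refset.archetypes["I"], ref, ann)
        assert rep.lipase_box == "GHSMG"
        assert rep.n_disulfides == 1
        assert not rep.extended_loop_present
        assert rep.clamp_present is True

    def test_structure_inputs_mark_report(self, refset, ref, ann):
        q = refset.archetypes["III"]
        spec = refset.specs["III"]
        st = synth.make_toy_structure(q, synth._own_triad("III"), spec.cys_pairs)
        from petype.structure import read_pdb

        rep = extract_features(q, ref, ann, model=None)
        assert rep.structure_derived is False

    def test_report_serializes(self, refset, ref, ann):
        import json

        rep = extract_features(refset.archetypes["IIa"], ref, ann)
        parsed = json.loads(rep.to_json())
        assert parsed["query_id"] == "arch_IIa"
        assert "lipase box" in rep.to_text()


def test_annotation_tsv_round_trip(tmp_path, ann):
    p = tmp_path / "ann.tsv"
    write_annotation_tsv(ann, p)
    assert read_annotation_tsv(p) == ann
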