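"""MoRF candidate detection, alignment mapping and conservation calling."""

import numpy as np
import pytest

from idrscape.disorder import DisorderTrack
from idrscape.morf import (
    MorfSegment,
    _best_offset_identity,
    ap2_morf_layout,
    call_conserved,
    dip_candidates,
    flag_exclusive,
    map_to_alignment,
    read_external_morfs,
)
from idrscape.seqio import ProteinRecord, RegionAnnotation


def _track(scores, pid="p"):
    return DisorderTrack(pid, np.asarray(scores, dtype=float))


class TestDipCandidates:
    def test_step_track(self):
        scores = [0.8] * 30 + [0.3] * 10 + [0.8] * 30
        segs = dip_candidates(_track(scores))
        assert [(s.start, s.end) for s in segs] == [(30, 40)]
        assert segs[0].mean_score == pytest.approx(0.3)

    def test_short_dip_rejected(self):
        scores = [0.8] * 30 + [0.3] * 3 + [0.8] * 30
        assert dip_candidates(_track(scores)) == []

    def test_long_dip_rejected(self):
        scores = [0.8] * 30 + [0.3] * 30 + [0.8] * 30
        assert dip_candidates(_track(scores)) == []

    def test_edge_dip_one_sided_context(self):
        scores = [0.3] * 8 + [0.8] * 30
        segs = dip_candidates(_track(scores))
        assert [(s.start, s.end) for s in segs] == [(0, 8)]

    def test_low_context_rejected(self):
        # a near-dip in the left context pulls its mean below threshold
        scores = [0.8] * 4 + [0.05] * 4 + [0.55] * 2 + [0.3] * 8 + [0.8] * 30
        assert dip_candidates(_track(scores)) == []

    def test_ap2_overlap_excluded(self):
        scores = [0.8] * 30 + [0.3] * 10 + [0.8] * 30
        regions = [RegionAnnotation("AP2", 35, 60)]
        assert dip_candidates(_track(scores), regions) == []

    def test_recovers_planted_dips(self, default_family):
        # emitted tracks dip at the planted motifs; the dip detector should
        # find most of them at default parameters
        found = 0
        total = 0
        for rec in default_family.records:
            track = default_family.tracks[rec.id]
            segs = dip_candidates(track, rec.regions)
            planted = [
                (m.start, m.end)
                for m in default_family.truth.morfs
                if m.protein_id == rec.id
            ]
            total += len(planted)
            for ps, pe in planted:
                if any(s.start < pe and ps < s.end for s in segs):
                    found += 1
        assert found / total > 0.8


class TestReadExternal:
    def _records(self):
        return [ProteinRecord("p1", "A" * 30)]

    def test_span_schema(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("id\tstart\tend\np1\t12\t20\n")
        segs = read_external_morfs(p, self._records())
        assert [(s.start, s.end) for s in segs] == [(11, 20)]

    def test_score_schema(self, tmp_path):
        p = tmp_path / "m.tsv"
        rows = ["id\tposition\tscore"]
        for pos in range(1, 31):
            score = 0.9 if 10 <= pos <= 15 else 0.1
            rows.append(f"p1\t{pos}\t{score}")
        p.write_text("\n".join(rows) + "\n")
        segs = read_external_morfs(p, self._records(), score_threshold=0.725)
        assert [(s.start, s.end) for s in segs] == [(9, 15)]

    def test_overlapping_rows_merged(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("id\tstart\tend\np1\t5\t12\np1\t10\t18\n")
        segs = read_external_morfs(p, self._records())
        assert [(s.start, s.end) for s in segs] == [(4, 18)]

    def test_span_outside_sequence_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("id\tstart\tend\np1\t25\t40\n")
        with pytest.raises(ValueError, match="outside"):
            read_external_morfs(p, self._records())


class TestAlignmentMapping:
    def test_gap_arithmetic(self):
        msa = {"p": "A-CD"}
        seg = MorfSegment("p", 1, 3)
        [(_, c0, c1)] = map_to_alignment(msa, [seg])
        assert (c0, c1) == (2, 4)

    def test_full_sequence_span(self):
        msa = {"p": "-AB--C-"}
        seg = MorfSegment("p", 0, 3)
        [(_, c0, c1)] = map_to_alignment(msa, [seg])
        assert (c0, c1) == (1, 6)

    def test_round_trip_identity(self):
        msa = {"p": "AB--CDE-FG"}
        cols = [i for i, c in enumerate(msa["p"]) if c != "-"]
        for start in range(6):
            for end in range(start + 1, 7):
                [(_, c0, c1)] = map_to_alignment(
                    msa, [MorfSegment("p", start, end)]
                )
                back = [i for i, c in enumerate(cols) if c0 <= c < c1]
                assert (back[0], back[-1] + 1) == (start, end)

    def test_missing_protein_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            map_to_alignment({"q": "AAAA"}, [MorfSegment("p", 0, 2)])


class TestCallConserved:
    def _family(self):
        members = [f"m{i}" for i in range(6)]
        msa = {m: "Q" * 10 + "MGTIF" + "Q" * 10 for m in members}  # motif [10,15)
        morfs = [MorfSegment(m, 10, 15) for m in members]
        return members, msa, morfs

    def test_full_occupancy_single_call(self):
        members, msa, morfs = self._family()
        calls = call_conserved("SG", members, msa, morfs)
        assert len(calls) == 1
        assert calls[0].occupancy == 1.0
        assert calls[0].consensus == "MGTIF"

    def test_low_occupancy_not_called(self):
        members, msa, morfs = self._family()
        calls = call_conserved("SG", members, msa, morfs[:3])  # 3/6 members
        assert calls == []

    def test_naming_both_sides_of_ap2(self):
        members = [f"m{i}" for i in range(4)]
        seq = "D" * 12 + "W" * 20 + "E" * 14
        msa = {m: seq for m in members}
        ap2 = {m: [(12, 32)] for m in members}
        morfs = [MorfSegment(m, 2, 9) for m in members] + [
            MorfSegment(m, 34, 42) for m in members
        ]
        calls = call_conserved("IIIc", members, msa, morfs, ap2)
        assert sorted(c.name for c in calls) == ["IIIc C1", "IIIc N1"]
        by_side = {c.side: c for c in calls}
        assert by_side["N"].col_span[0] < by_side["C"].col_span[0]

    def test_permutation_invariance(self):
        members, msa, morfs = self._family()
        fwd = call_conserved("SG", members, msa, morfs)
        rev = call_conserved("SG", members[::-1], msa, morfs[::-1])
        assert [(c.name, c.occupancy, c.consensus) for c in fwd] == [
            (c.name, c.occupancy, c.consensus) for c in rev
        ]

    def test_occupancy_recomputes_from_member_hits(self, default_family):
        fam = default_family
        for sub in sorted(set(fam.subgroups.values())):
            members = [p for p, s in fam.subgroups.items() if s == sub]
            msa = fam.subgroup_msas[sub]
            ap2 = {
                pid: [fam.truth.ap2_spans[pid]] for pid in members
            }
            segs = [m for m in fam.morf_table if m.protein_id in set(members)]
            for call in call_conserved(sub, members, msa, segs, ap2):
                assert call.occupancy == pytest.approx(
                    len(call.member_hits) / len(members)
                )

    def test_indices_consecutive_and_ordered(self):
        members = [f"m{i}" for i in range(4)]
        seq = "D" * 60
        msa = {m: seq for m in members}
        morfs = []
        for m in members:
            morfs += [MorfSegment(m, 5, 12), MorfSegment(m, 25, 33),
                      MorfSegment(m, 45, 52)]
        calls = call_conserved("G", members, msa, morfs)
        names = [c.name for c in calls]
        assert names == ["G N1", "G N2", "G N3"]
        starts = [c.col_span[0] for c in calls]
        assert starts == sorted(starts)


class TestExclusivity:
    def test_unique_motif_exclusive(self):
        from idrscape.morf import ConservedMorf

        a = ConservedMorf("A N1", "A", "N", {}, (0, 10), 1.0, "LDLNLNLELR")
        b = ConservedMorf("B N1", "B", "N", {}, (0, 10), 1.0, "DEDEYDSDDE")
        out = flag_exclusive([a, b])
        assert a.exclusive and b.exclusive

    def test_shared_motif_not_exclusive(self):
        from idrscape.morf import ConservedMorf

        a = ConservedMorf("A C1", "A", "C", {}, (0, 10), 1.0, "TDDMLWSYLN")
        b = ConservedMorf("B C1", "B", "C", {}, (0, 10), 1.0, "TDDMLWSYLN")
        flag_exclusive([a, b])
        assert not a.exclusive and not b.exclusive

    def test_vacuous_when_alone(self):
        from idrscape.morf import ConservedMorf

        a = ConservedMorf("A C1", "A", "C", {}, (0, 10), 1.0, "TDDMLWSYLN")
        flag_exclusive([a])
        assert a.exclusive

    def test_offset_identity(self):
        assert _best_offset_identity("ABCDE", "ABCDE") == 1.0
        assert _best_offset_identity("CDE", "ABCDEFG") == 1.0
        assert _best_offset_identity("AAAA", "TTTT") == 0.0


class TestAp2Layout:
    def _records_with_subregions(self):
        seq = "D" * 10 + "W" * 58 + "E" * 10
        regions = [
            RegionAnnotation("AP2", 10, 68),
            RegionAnnotation("BETA", 14, 24),
            RegionAnnotation("BETA", 27, 35),
            RegionAnnotation("BETA", 38, 46),
            RegionAnnotation("ALPHA", 50, 66),
        ]
        return [
            ProteinRecord(f"m{i}", seq, list(regions)) for i in range(2)
        ]

    def test_beta_only_morfs_leave_alpha_empty(self):
        from idrscape.morf import ConservedMorf

        recs = self._records_with_subregions()
        cm = ConservedMorf(
            "G AP2-1", "G", "AP2",
            {r.id: (14, 35) for r in recs}, (14, 35), 1.0, "W" * 10,
        )
        subgroups = {r.id: "G" for r in recs}
        layout = ap2_morf_layout([cm], recs, subgroups)
        assert layout.loc["G", "alpha"] == 0.0
        assert layout.loc["G", "beta1"] == 1.0
        assert layout.loc["G", "beta2"] == 1.0

    def test_domain_spanning_morfs_fill_all(self):
        from idrscape.morf import ConservedMorf

        recs = self._records_with_subregions()
        cm = ConservedMorf(
            "G AP2-1", "G", "AP2",
            {r.id: (10, 68) for r in recs}, (10, 68), 1.0, "W" * 10,
        )
        layout = ap2_morf_layout([cm], recs, {r.id: "G" for r in recs})
        assert (layout.loc["G"] == 1.0).all()

    def test_no_ap2_morfs_all_zero(self):
        recs = self._records_with_subregions()
        layout = ap2_morf_layout([], recs, {r.id: "G" for r in recs})
        assert (layout.loc["G"] == 0.0).all()

    def test_missing_subannotation_rejected(self):
        from idrscape.morf import ConservedMorf

        rec = ProteinRecord(
            "m0", "D" * 10 + "W" * 58 + "E" * 10,
            [RegionAnnotation("AP2", 10, 68)],
        )
        cm = ConservedMorf(
            "G AP2-1", "G", "AP2", {"m0": (14, 35)}, (14, 35), 1.0, "W",
        )
        with pytest.raises(ValueError, match="m0"):
            ap2_morf_layout([cm], [rec], {"m0": "G"})
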