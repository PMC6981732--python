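"""Charge-hydropathy, CDF and combined quadrant classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from idrscape.disorder import (
    calibrate_cdf_boundary,
    cdf_curve,
    ch_distance,
    ch_point,
    chcdf_quadrant,
    default_cdf_boundary,
    idaa_fraction,
    internal_track,
    kd_hydropathy,
    mean_net_charge,
    read_track,
    write_track,
)
from idrscape.seqio import ProteinRecord


class TestHydropathy:
    def test_most_hydrophobic_homopolymer(self):
        # KD(I) = 4.5 rescales to 1.0
        assert kd_hydropathy("IIIII", window=5) == pytest.approx(1.0)

    def test_least_hydrophobic_homopolymer(self):
        # KD(R) = -4.5 rescales to 0.0
        assert kd_hydropathy("RRRRR", window=5) == pytest.approx(0.0)

    def test_window_irrelevant_on_homopolymer(self):
        seq = "L" * 21
        assert kd_hydropathy(seq, 1) == pytest.approx(kd_hydropathy(seq, 21))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            kd_hydropathy("", 1)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            kd_hydropathy("ILVA", 2)


class TestNetCharge:
    @pytest.mark.parametrize(
        "seq, expected",
        [("EEEEK", 0.6), ("KRDE", 0.0), ("AAAA", 0.0), ("KKKKK", 1.0)],
    )
    def test_values(self, seq, expected):
        assert mean_net_charge(seq) == pytest.approx(expected)

    def test_histidine_neutral_by_default(self):
        assert mean_net_charge("HHHH") == 0.0
        assert mean_net_charge("HHHH", histidine_charged=True) == 1.0


class TestCHDistance:
    def test_arithmetic(self):
        assert ch_distance(0.5, 0.3) == pytest.approx(0.0585)

    def test_point_on_boundary(self):
        h = 0.6
        assert ch_distance(h, 2.785 * h - 1.151) == pytest.approx(0.0)

    def test_hydrophobic_extreme(self):
        assert ch_distance(1.0, 0.0) == pytest.approx(-1.634)

    def test_perpendicular_shares_sign(self):
        p = ch_point("EEEEEKKKDDD" * 5)
        assert np.sign(p.ch_perpendicular) == np.sign(p.ch_distance)
        assert abs(p.ch_perpendicular) < abs(p.ch_distance)


class TestInternalTrack:
    def test_poly_e_scores_disordered(self):
        tr = internal_track("E" * 40)
        assert (tr.scores > 0.5).all()

    def test_poly_i_scores_ordered(self):
        tr = internal_track("I" * 40)
        assert (tr.scores < 0.5).all()

    def test_flanks_score_above_domain(self, default_family):
        rec = default_family.records[0]
        s, e = default_family.truth.ap2_spans[rec.id]
        tr = internal_track(rec.sequence)
        flank_mean = np.concatenate([tr.scores[:s], tr.scores[e:]]).mean()
        assert flank_mean > tr.scores[s:e].mean()

    def test_reversal_symmetry(self):
        seq = "MKEEDDRRLLIIVVAGSTPEEK"
        fwd = internal_track(seq, window=5).scores
        rev = internal_track(seq[::-1], window=5).scores
        assert np.allclose(fwd, rev[::-1])


class TestTrackIO:
    def _records(self):
        return [ProteinRecord("p1", "MKV")]

    def test_round_trip(self, tmp_path, default_family):
        path = tmp_path / "tracks.tsv"
        write_track(default_family.tracks, default_family.records, path)
        back = read_track(path, default_family.records)
        for pid, tr in default_family.tracks.items():
            assert np.allclose(back[pid].scores, tr.scores, atol=1e-6)

    def test_residue_mismatch_rejected(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(
            "id\tposition\tresidue\tscore\n"
            "p1\t1\tM\t0.5\np1\t2\tA\t0.5\np1\t3\tV\t0.5\n"
        )
        with pytest.raises(ValueError, match="residues"):
            read_track(path, self._records())

    def test_position_gap_rejected(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(
            "id\tposition\tresidue\tscore\np1\t1\tM\t0.5\np1\t3\tV\t0.5\n"
        )
        with pytest.raises(ValueError, match="positions"):
            read_track(path, self._records())

    def test_out_of_range_scores_clamped(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(
            "id\tposition\tresidue\tscore\n"
            "p1\t1\tM\t1.2\np1\t2\tK\t0.5\np1\t3\tV\t-0.1\n"
        )
        tracks = read_track(path, self._records())
        assert tracks["p1"].scores.max() == 1.0
        assert tracks["p1"].scores.min() == 0.0


class TestCDF:
    def test_fully_disordered_limit(self):
        curve = cdf_curve(np.ones(50))
        assert (curve.cdf_values == 0).all()

    def test_fully_ordered_limit(self):
        curve = cdf_curve(np.zeros(50))
        assert (curve.cdf_values == 1).all()

    def test_two_point_distribution(self):
        scores = np.array([0.25] * 25 + [0.75] * 25)
        curve = cdf_curve(scores)
        mid = (curve.bin_scores >= 0.3) & (curve.bin_scores <= 0.7)
        assert np.allclose(curve.cdf_values[mid], 0.5)

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError):
            cdf_curve(np.array([]))

    @settings(derandomize=True, max_examples=100)
    @given(
        scores=st.lists(
            st.floats(0, 1, allow_nan=False), min_size=1, max_size=200
        )
    )
    def test_monotone_and_bounded(self, scores):
        curve = cdf_curve(np.array(scores))
        assert (np.diff(curve.cdf_values) >= 0).all()
        assert curve.cdf_values.min() >= 0 and curve.cdf_values.max() <= 1

    def test_distance_sign_convention(self):
        boundary = default_cdf_boundary()
        ordered = cdf_curve(np.full(100, 0.1), boundary=boundary)
        disordered = cdf_curve(np.full(100, 0.9), boundary=boundary)
        assert ordered.cdf_distance > 0 > disordered.cdf_distance

    def test_calibration_midpoint(self):
        rng = np.random.default_rng(0)
        ordered = [rng.beta(2, 8, 100) for _ in range(10)]
        disordered = [rng.beta(8, 2, 100) for _ in range(10)]
        boundary = calibrate_cdf_boundary(ordered, disordered)
        mean_ord = np.mean([cdf_curve(t).cdf_values for t in ordered], axis=0)
        mean_dis = np.mean([cdf_curve(t).cdf_values for t in disordered], axis=0)
        assert np.allclose(boundary, (mean_ord + mean_dis) / 2)


class TestQuadrants:
    @pytest.mark.parametrize(
        "ch, cdf, expected",
        [
            (+0.05, +0.1, "Q1"),   # CH disordered, CDF ordered
            (-0.05, +0.1, "Q2"),   # ordered by both
            (-0.05, -0.1, "Q3"),   # CDF disordered, CH compact
            (+0.05, -0.1, "Q4"),   # disordered by both
        ],
    )
    def test_truth_table(self, ch, cdf, expected):
        assert chcdf_quadrant(ch, cdf) == expected

    def test_exhaustive_and_exclusive(self):
        seen = {
            chcdf_quadrant(ch, cdf)
            for ch in (-1, -0.1, 0.1, 1)
            for cdf in (-1, -0.1, 0.1, 1)
        }
        assert seen == {"Q1", "Q2", "Q3", "Q4"}

    def test_zero_resolves_to_ordered_call(self):
        assert chcdf_quadrant(0.0, 0.1) == "Q2"   # CH zero -> not disordered
        assert chcdf_quadrant(0.1, 0.0) == "Q1"   # CDF zero -> ordered
        assert chcdf_quadrant(0.0, 0.0) == "Q2"


class TestIdaa:
    def test_direct_count(self):
        assert idaa_fraction(np.array([0.6, 0.6, 0.4, 0.5])) == pytest.approx(75.0)

    def test_saturated(self):
        assert idaa_fraction(np.array([0.5, 0.9, 1.0])) == 100.0

    def test_empty_above_threshold(self):
        assert idaa_fraction(np.array([0.1, 0.2, 0.49])) == 0.0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        scores = rng.random(500)
        vals = [idaa_fraction(scores, t) for t in np.linspace(0.05, 0.95, 19)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_compositional_mode(self):
        assert idaa_fraction("AEKS", mode="composition") == 100.0
        assert idaa_fraction("ILVW", mode="composition") == 0.0


class TestCHSeparationDesignedExtremes:
    def test_charged_vs_hydrophobic(self):
        rng = np.random.default_rng(42)
        charged_pool = list("EDKRSG")
        hydrophobic_pool = list("ILVFAM")
        for _ in range(50):
            charged = "".join(rng.choice(charged_pool, size=80))
            hydro = "".join(rng.choice(hydrophobic_pool, size=80))
            assert ch_point(charged).ch_distance > 0
            assert ch_point(hydro).ch_distance < 0
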