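"""Gait metrics: time normalisation, trial averaging, GVS/GPS, foot
progression angle, symmetry index and reference building."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitprofile.errors import GeometryError, ValidationError
from gaitprofile.metrics import (VARIABLES, GaitCycleWaveforms, GPSScore, GVSVector,
                                 ReferenceProfile, age_group_of, average_trials,
                                 build_reference, foot_progression_angle, gps, gvs,
                                 symmetry_index, time_normalise)


def make_waveforms(values, side="right", **meta):
    return GaitCycleWaveforms(values=np.asarray(values, float), side=side, meta=meta)


def make_reference(values, group="children"):
    return ReferenceProfile(values=np.asarray(values, float), n_subjects=1,
                            age_group=group)


class TestTimeNormalise:
    times = np.linspace(0.0, 2.0, 401)

    def test_constant_signal(self):
        out = time_normalise(np.full(401, 7.0), self.times, 0.2, 1.4, T=101)
        np.testing.assert_allclose(out, 7.0)
        assert out.size == 101

    def test_linear_ramp_exact(self):
        out = time_normalise(3.0 * self.times - 1.0, self.times, 0.25, 1.75, T=51)
        np.testing.assert_allclose(out, np.linspace(3 * 0.25 - 1, 3 * 1.75 - 1, 51),
                                   atol=1e-12)

    def test_sine_at_200hz(self):
        t = np.arange(0, 1.5, 1 / 200)
        out = time_normalise(np.sin(2 * np.pi * t), t, 0.0, 1.0, T=101)
        want = np.sin(2 * np.pi * np.linspace(0, 1, 101))
        assert np.abs(out - want).max() < 1e-3

    def test_events_outside_trial(self):
        with pytest.raises(ValidationError):
            time_normalise(self.times, self.times, -0.5, 1.0)
        with pytest.raises(ValidationError):
            time_normalise(self.times, self.times, 1.0, 0.5)


class TestAverageTrials:
    def test_single_input_identity(self):
        w = make_waveforms(np.random.default_rng(0).normal(size=(9, 101)))
        np.testing.assert_array_equal(average_trials([w]).values, w.values)

    def test_symmetric_pair_recovers_template(self):
        template = np.random.default_rng(1).normal(size=(9, 51))
        d = np.random.default_rng(2).normal(size=(9, 51))
        out = average_trials([make_waveforms(template + d), make_waveforms(template - d)])
        np.testing.assert_allclose(out.values, template, atol=1e-12)

    def test_elementwise_oracle(self, rng):
        ws = [make_waveforms(rng.normal(size=(9, 31))) for _ in range(5)]
        out = average_trials(ws)
        want = sum(w.values for w in ws) / 5
        np.testing.assert_allclose(out.values, want, atol=1e-12)

    def test_grid_and_side_mismatch(self):
        with pytest.raises(ValidationError):
            average_trials([make_waveforms(np.zeros((9, 10))),
                            make_waveforms(np.zeros((9, 11)))])
        with pytest.raises(ValidationError):
            average_trials([make_waveforms(np.zeros((9, 10))),
                            make_waveforms(np.zeros((9, 10)), side="left")])


class TestGVSGPS:
    def test_zero_deviation(self):
        x = np.random.default_rng(3).normal(size=(9, 101))
        v = gvs(make_waveforms(x), make_reference(x))
        np.testing.assert_array_equal(v.scores, 0.0)
        assert gps(v).value == 0.0

    def test_constant_offset_single_variable(self):
        ref = np.zeros((9, 101))
        x = ref.copy()
        x[4] += 3.0
        v = gvs(make_waveforms(x), make_reference(ref))
        assert v.scores[4] == pytest.approx(3.0)
        assert np.all(v.scores[[i for i in range(9) if i != 4]] == 0.0)

    def test_brute_force_oracle(self, rng):
        for _ in range(20):
            x, ref = rng.normal(size=(2, 9, 41))
            v = gvs(make_waveforms(x), make_reference(ref))
            want = [np.sqrt(sum((x[i, t] - ref[i, t]) ** 2 for t in range(41)) / 41)
                    for i in range(9)]
            np.testing.assert_allclose(v.scores, want, atol=1e-12)
            g = gps(v)
            assert g.value == pytest.approx(
                np.sqrt(sum(s ** 2 for s in want) / 9), abs=1e-12)

    def test_gps_of_two_scores(self):
        g = gps(GVSVector(scores=np.array([3.0, 4.0]), limb="right"))
        assert g.value == pytest.approx(np.sqrt(12.5), abs=1e-12)
        assert g.N == 2

    def test_gps_permutation_invariant(self, rng):
        s = rng.uniform(0, 10, 9)
        g1 = gps(GVSVector(scores=s, limb="right"))
        g2 = gps(GVSVector(scores=np.flip(s), limb="right"))
        assert g1.value == pytest.approx(g2.value, abs=1e-12)

    def test_gps_bracketed_by_gvs(self, rng):
        s = rng.uniform(0, 10, 9)
        g = gps(GVSVector(scores=s, limb="right"))
        assert s.min() <= g.value <= s.max()

    def test_empty_vector_rejected(self):
        with pytest.raises(ValidationError):
            gps(GVSVector(scores=np.array([]), limb="right"))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 5.0))
    def test_scale_property(self, seed, c):
        """Scaling all deviations by c scales every GVS and the GPS by c."""
        r = np.random.default_rng(seed)
        ref = r.normal(size=(9, 21))
        dev = r.normal(size=(9, 21))
        v1 = gvs(make_waveforms(ref + dev), make_reference(ref))
        vc = gvs(make_waveforms(ref + c * dev), make_reference(ref))
        np.testing.assert_allclose(vc.scores, c * v1.scores, atol=1e-9)
        assert gps(vc).value == pytest.approx(c * gps(v1).value, abs=1e-9)

    def test_gps_strictly_monotone_in_each_gvs(self, rng):
        s = rng.uniform(1, 5, 9)
        base = gps(GVSVector(scores=s, limb="right")).value
        for i in range(9):
            bumped = s.copy()
            bumped[i] += 0.5
            assert gps(GVSVector(scores=bumped, limb="right")).value > base


class TestFootProgression:
    times = np.linspace(0, 1, 201)

    def _trajs(self, foot_angle_deg=0.0):
        n = self.times.size
        pelvis = np.column_stack([self.times * 1.2, np.zeros(n), np.full(n, 0.9)])
        ankle = np.column_stack([self.times * 1.2, np.full(n, -0.1), np.full(n, 0.07)])
        ang = np.radians(foot_angle_deg)
        foot_vec = np.array([0.15 * np.cos(ang), 0.15 * np.sin(ang), -0.04])
        return pelvis, ankle, ankle + foot_vec

    def test_parallel_foot_gives_zero(self):
        pelvis, ankle, toe = self._trajs(0.0)
        out = foot_progression_angle(pelvis, ankle, toe, self.times, 0, 1, side="right")
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    @pytest.mark.parametrize("side,sign", [("right", 1.0), ("left", -1.0)])
    def test_rotated_foot_constant_angle(self, side, sign):
        # +10 deg about vertical is toward the left: in-toeing for the right
        # foot, out-toeing for the left
        pelvis, ankle, toe = self._trajs(10.0)
        out = foot_progression_angle(pelvis, ankle, toe, self.times, 0, 1, side=side)
        np.testing.assert_allclose(out, sign * 10.0, atol=1e-9)

    def test_vertical_components_ignored(self, rng):
        pelvis, ankle, toe = self._trajs(7.0)
        out1 = foot_progression_angle(pelvis, ankle, toe, self.times, 0, 1, side="right")
        bumpy = toe.copy()
        bumpy[:, 2] += rng.normal(size=toe.shape[0])
        pelvis2 = pelvis.copy()
        pelvis2[:, 2] += rng.normal(size=toe.shape[0])
        out2 = foot_progression_angle(pelvis2, ankle, bumpy, self.times, 0, 1,
                                      side="right")
        np.testing.assert_allclose(out1, out2, atol=1e-12)

    def test_zero_progression_degenerate(self):
        n = self.times.size
        pelvis = np.tile([0.0, 0.0, 0.9], (n, 1))
        ankle = np.tile([0.0, -0.1, 0.07], (n, 1))
        with pytest.raises(GeometryError):
            foot_progression_angle(pelvis, ankle, ankle + [0.15, 0, -0.04],
                                   self.times, 0, 1, side="right")


class TestSymmetryIndex:
    def test_equal_limbs(self):
        assert symmetry_index(GPSScore(5.0, 9, "left"), GPSScore(5.0, 9, "right")) == 0.0

    def test_robinson_formula(self):
        assert symmetry_index(GPSScore(6.0, 9, "left"),
                              GPSScore(4.0, 9, "right")) == pytest.approx(40.0)

    def test_antisymmetry(self, rng):
        a, b = rng.uniform(1, 10, 2)
        assert symmetry_index(GPSScore(a, 9, "left"), GPSScore(b, 9, "right")) == \
            pytest.approx(-symmetry_index(GPSScore(b, 9, "left"), GPSScore(a, 9, "right")))

    def test_both_zero_undefined(self):
        with pytest.raises(ValidationError):
            symmetry_index(GPSScore(0.0, 9, "left"), GPSScore(0.0, 9, "right"))


class TestBuildReference:
    def test_age_group_boundaries(self):
        assert age_group_of(9.9) == "children"
        assert age_group_of(10.0) == "teenagers"
        assert age_group_of(16.0) == "young_adults"

    def test_single_subject_per_group(self, rng):
        ws = [make_waveforms(rng.normal(size=(9, 21)), subject=f"s{i}")
              for i in range(3)]
        refs = build_reference(ws, [7.0, 12.0, 20.0])
        np.testing.assert_array_equal(refs["children"].values, ws[0].values)
        np.testing.assert_array_equal(refs["teenagers"].values, ws[1].values)
        np.testing.assert_array_equal(refs["young_adults"].values, ws[2].values)

    def test_symmetric_cohort_recovers_template(self, rng):
        template = rng.normal(size=(9, 21))
        d = rng.normal(size=(9, 21))
        ws = [make_waveforms(template + d), make_waveforms(template - d),
              make_waveforms(template, subject="t"), make_waveforms(template, subject="a")]
        refs = build_reference(ws, [5.0, 5.0, 12.0, 20.0])
        np.testing.assert_allclose(refs["children"].values, template, atol=1e-12)

    def test_variance_decomposition(self, rng):
        # mean over limbs of GPS^2 against the group mean equals the average
        # (over variables and time) within-group variance (n denominator)
        ws = [make_waveforms(rng.normal(size=(9, 31))) for _ in range(8)]
        ages = [7.0] * 8 + []
        refs = build_reference(ws + [make_waveforms(np.zeros((9, 31)))] * 2,
                               ages + [12.0, 20.0])
        ref = refs["children"]
        gps_sq = [gps(gvs(w, ref)).value ** 2 for w in ws]
        stacked = np.stack([w.values for w in ws])
        want = stacked.var(axis=0).mean()
        assert np.mean(gps_sq) == pytest.approx(want, abs=1e-12)

    def test_empty_group_rejected(self, rng):
        ws = [make_waveforms(rng.normal(size=(9, 11)))]
        with pytest.raises(ValidationError):
            build_reference(ws, [7.0])
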