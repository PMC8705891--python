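"""Outcome statistics: responder classification, waveform similarity,
Bland-Altman, paired tests, permutation waveform test and Kruskal-Wallis/Dunn."""

import numpy as np
import pytest
from scipy import stats as sps

from gaitprofile.errors import ResolutionError, ValidationError
from gaitprofile.metrics import VARIABLES, GaitCycleWaveforms
from gaitprofile.stats import (OutcomeRecord, bland_altman, classify_responder,
                               group_axis_comparison, paired_tests,
                               pointwise_waveform_test, tabulate_agreement,
                               waveform_r2, waveform_rmsd)


def make_waveforms(values, side="right"):
    return GaitCycleWaveforms(values=np.asarray(values, float), side=side)


class TestClassifyResponder:
    @pytest.mark.parametrize("delta,label", [
        (-1.6, "responder"),          # boundary inclusive
        (-1.59, "non-responder"),
        (5.0, "non-responder"),
        (-10.0, "responder"),
    ])
    def test_mcid_criterion(self, delta, label):
        assert classify_responder(delta) == label

    def test_monotone_in_delta(self):
        deltas = np.linspace(-5, 5, 201)
        labels = [classify_responder(d) == "responder" for d in deltas]
        # once a delta stops qualifying, no larger delta qualifies again
        assert labels == sorted(labels, reverse=True)

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            classify_responder(float("nan"))


class TestWaveformSimilarity:
    def test_rmsd_identical_and_offset(self, rng):
        x = rng.normal(size=(9, 101))
        assert all(v == 0 for v in waveform_rmsd(make_waveforms(x),
                                                 make_waveforms(x)).values())
        off = waveform_rmsd(make_waveforms(x + 5.0), make_waveforms(x))
        assert all(abs(v - 5.0) < 1e-12 for v in off.values())

    def test_rmsd_brute_force(self, rng):
        a, b = rng.normal(size=(2, 9, 31))
        got = waveform_rmsd(make_waveforms(a), make_waveforms(b))
        for i, var in enumerate(VARIABLES):
            want = np.sqrt(np.mean((a[i] - b[i]) ** 2))
            assert abs(got[var] - want) < 1e-12

    def test_r2_perfect_linear_relation(self, rng):
        a = rng.normal(size=(9, 101))
        b = 2.0 * a + 3.0
        got = waveform_r2(make_waveforms(a), make_waveforms(b))
        assert all(abs(v - 1.0) < 1e-9 for v in got.values())
        same = waveform_r2(make_waveforms(a), make_waveforms(a))
        assert all(abs(v - 1.0) < 1e-12 for v in same.values())

    def test_r2_normal_equations_oracle(self, rng):
        a, b = rng.normal(size=(2, 9, 41))
        got = waveform_r2(make_waveforms(a), make_waveforms(b))
        for i, var in enumerate(VARIABLES):
            res = sps.linregress(b[i], a[i])
            assert abs(got[var] - res.rvalue ** 2) < 1e-9

    def test_r2_constant_predictor(self, rng):
        a = rng.normal(size=(9, 11))
        with pytest.raises(ValidationError):
            waveform_r2(make_waveforms(a), make_waveforms(np.ones((9, 11))))


class TestBlandAltman:
    def test_hand_computed_example(self):
        ba = bland_altman([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])   # diffs {1,2,3}
        assert ba.bias == pytest.approx(2.0)
        assert ba.sd == pytest.approx(1.0)
        assert ba.loa_low == pytest.approx(0.04)
        assert ba.loa_high == pytest.approx(3.96)

    def test_identical_samples(self, rng):
        x = rng.normal(size=10)
        ba = bland_altman(x, x)
        assert ba.bias == 0.0 and ba.loa_low == 0.0 and ba.loa_high == 0.0

    def test_antisymmetry(self, rng):
        x, y = rng.normal(size=(2, 12))
        f, r = bland_altman(x, y), bland_altman(y, x)
        assert f.bias == pytest.approx(-r.bias)
        assert f.loa_low == pytest.approx(-r.loa_high)
        assert f.loa_high == pytest.approx(-r.loa_low)

    def test_limits_bracket_bias(self, rng):
        x, y = rng.normal(size=(2, 20))
        ba = bland_altman(x, y)
        assert ba.loa_low <= ba.bias <= ba.loa_high
        assert ba.loa_high - ba.loa_low == pytest.approx(2 * 1.96 * ba.sd)

    def test_too_few_pairs(self):
        with pytest.raises(ValidationError):
            bland_altman([1.0], [2.0])


class TestPairedTests:
    def test_identical_vectors_spearman(self):
        rho, _, _ = paired_tests([1, 2, 3, 4], [1, 2, 3, 4], "spearman")
        assert rho == pytest.approx(1.0)

    def test_monotone_transform(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.exp(x)
        rho, _, _ = paired_tests(x, y, "spearman")
        r, _, _ = paired_tests(x, y, "pearson")
        assert rho == pytest.approx(1.0)
        assert r < 1.0

    def test_spearman_hand_enumerated(self):
        # ranks of y: 1,3,2,4 -> sum d^2 = 2 -> rho = 1 - 12/60 = 0.8
        rho, _, _ = paired_tests([1, 2, 3, 4], [10, 30, 20, 40], "spearman")
        assert rho == pytest.approx(0.8)

    def test_wilcoxon_matches_scipy_reference(self):
        x = np.array([1.2, 2.1, 2.9, 4.4, 5.0, 6.3])
        y = np.array([1.0, 2.6, 2.9, 4.0, 5.5, 6.0])
        stat, p, note = paired_tests(x, y, "wilcoxon")
        want = sps.wilcoxon(x, y, zero_method="wilcox")
        assert stat == pytest.approx(float(want.statistic))
        assert p == pytest.approx(float(want.pvalue))
        assert "zeros dropped" in note

    def test_validation(self):
        with pytest.raises(ValidationError):
            paired_tests([1, 2, 3], [1, 2], "spearman")
        with pytest.raises(ValidationError):
            paired_tests([1, 2], [1, 2], "spearman")
        with pytest.raises(ValidationError):
            paired_tests([1, 2, 3], [1, 2, 3], "anova")


class TestPointwiseWaveformTest:
    def test_identical_groups_no_significance(self, rng):
        A = rng.normal(size=(8, 9, 51))
        res = pointwise_waveform_test(A, A.copy(), n_permutations=200, seed=0)
        assert all(not m.any() for m in res.masks.values())

    def test_bonferroni_alpha(self, rng):
        A = rng.normal(size=(6, 9, 21))
        B = rng.normal(size=(6, 9, 21))
        res = pointwise_waveform_test(A, B, alpha_family=0.05, n_comparisons=9,
                                      n_permutations=1000, seed=0)
        assert round(res.alpha_per_test, 4) == 0.0056

    def test_constructed_shift_detected_in_right_region(self, rng):
        n, T = 12, 101
        A = rng.normal(0, 1.0, size=(n, 9, T))
        B = A + rng.normal(0, 0.1, size=(n, 9, T))
        B[:, 4, 50:] += 10.0 * 1.0        # 10x the noise sd on half the cycle
        res = pointwise_waveform_test(A, B, n_permutations=1000, seed=1)
        mask = res.masks["hip_abduction"]
        assert mask[50:].mean() > 0.9
        assert mask[:50].mean() < 0.1
        assert all(not res.masks[v].any() for v in res.masks if v != "hip_abduction")

    def test_insufficient_permutations(self, rng):
        A = rng.normal(size=(5, 9, 11))
        with pytest.raises(ResolutionError):
            pointwise_waveform_test(A, A, n_permutations=100, seed=0)


class TestGroupAxisComparison:
    def test_identical_groups_zero_dunn(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        res = group_axis_comparison({"a": g, "b": g.copy()})
        assert res.pairwise["z"].abs().max() == pytest.approx(0.0)

    def test_extreme_separation(self, rng):
        res = group_axis_comparison({
            "a": rng.normal(0, 1, 15), "b": rng.normal(0, 1, 15),
            "c": rng.normal(50, 1, 15)})
        assert res.p_omnibus < 1e-3
        pair = res.pairwise.set_index(["group_a", "group_b"])
        assert pair.loc[("a", "c"), "p_bonferroni"] < 0.01
        assert pair.loc[("a", "b"), "p_unadjusted"] > 0.05

    def test_null_p_values_uniform(self):
        # calibration oracle: omnibus p under identical distributions is
        # approximately uniform across seeds (Kolmogorov-Smirnov check)
        ps = []
        for seed in range(200):
            r = np.random.default_rng(seed)
            res = group_axis_comparison({k: r.normal(size=10) for k in "abc"})
            ps.append(res.p_omnibus)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_validation(self):
        with pytest.raises(ValidationError):
            group_axis_comparison({"a": [1.0, 2.0]})
        with pytest.raises(ValidationError):
            group_axis_comparison({"a": [1.0, 2.0], "b": [1.0]})


class TestAgreement:
    @staticmethod
    def record(subject, delta_dk, delta_ik, clinical, operated=True):
        return OutcomeRecord(subject=subject, limb="right", operated=operated,
                             gps_pre={"dk": 10.0, "ik": 10.0},
                             gps_post={"dk": 10.0 + delta_dk, "ik": 10.0 + delta_ik},
                             clinical_label=clinical)

    def test_delta_and_flags_consistent(self):
        rec = self.record("s1", -2.0, -1.0, "responder")
        assert rec.delta_gps["dk"] == pytest.approx(-2.0)
        assert rec.responder == {"dk": "responder", "ik": "non-responder"}

    def test_full_agreement(self):
        recs = [self.record(f"s{i}", -3.0, -2.5, "responder") for i in range(4)]
        s = tabulate_agreement(recs)
        assert s.n_limbs == 4
        assert s.engine_vs_clinical == {"dk": 4, "ik": 4}
        assert s.engine_concordance == 4 and s.discordant == []

    def test_threshold_straddling_case(self):
        recs = [self.record("s0", -1.7, -1.5, "responder")]
        s = tabulate_agreement(recs)
        assert s.engine_vs_clinical == {"dk": 1, "ik": 0}
        assert s.engine_concordance == 0
        assert s.discordant[0]["inter_engine_delta_diff"] == pytest.approx(0.2)

    def test_non_operated_limbs_filtered(self):
        recs = [self.record("s0", -3.0, -3.0, "responder"),
                self.record("s1", -3.0, -3.0, None, operated=False)]
        assert tabulate_agreement(recs).n_limbs == 1

    def test_missing_clinical_label_named(self):
        with pytest.raises(ValidationError, match="s0"):
            tabulate_agreement([self.record("s0", -3.0, -3.0, None)])
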