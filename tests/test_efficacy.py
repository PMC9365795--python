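"""Volume arithmetic, growth comparison, survival conversion, Kaplan–Meier,
Fisher's exact and power calculations, each against an independent oracle."""

import math
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from th1select.efficacy import (
    MouseCurve,
    SurvivalRecord,
    TumorStudy,
    compare_growth,
    fisher_exact,
    group_size,
    km_estimate,
    percent_inhibition,
    read_measurements,
    survival_at,
    to_survival,
    tumor_volume,
)
from th1select import synth


class TestTumorVolume:
    def test_unit_cube_coefficient(self):
        assert tumor_volume(1, 1, 1) == pytest.approx(0.5236)

    def test_cubic_scaling(self):
        assert tumor_volume(10, 10, 10) == pytest.approx(523.6)

    def test_degenerate_dimension(self):
        assert tumor_volume(0, 5, 5) == 0.0

    def test_negative_dimension_rejected(self):
        with pytest.raises(ValueError, match="width"):
            tumor_volume(1, -1, 1)

    @settings(max_examples=50, derandomize=True)
    @given(dims=st.tuples(st.floats(0, 30), st.floats(0, 30), st.floats(0, 30)),
           c=st.floats(0.1, 5))
    def test_symmetric_and_degree_three_homogeneous(self, dims, c):
        l, w, h = dims
        base = tumor_volume(l, w, h)
        assert tumor_volume(w, h, l) == pytest.approx(base)
        assert tumor_volume(c * l, c * w, c * h) == pytest.approx(
            c ** 3 * base, rel=1e-9)


class TestPercentInhibition:
    def test_printed_study_means(self):
        # multiantigen vaccine vs adjuvant, pre-implant immunization
        assert percent_inhibition(314, 50) == pytest.approx(84.076, abs=1e-3)
        # post-implant immunization means
        assert percent_inhibition(1650, 231) == pytest.approx(86.0)

    def test_identity_and_full_inhibition(self):
        assert percent_inhibition(500, 500) == 0.0
        assert percent_inhibition(500, 0) == 100.0

    def test_strictly_decreasing_in_treated_mean(self):
        vals = [percent_inhibition(300, t) for t in (0, 50, 100, 400)]
        assert vals == sorted(vals, reverse=True)
        assert vals[-1] < 0  # treated exceeding control goes negative

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError):
            percent_inhibition(0, 10)


def flat_curve(mouse, days, value):
    return MouseCurve(mouse, tuple(days), tuple([value] * len(days)))


class TestCompareGrowth:
    def test_identical_arms_null_case(self):
        days = (0, 2, 4)
        arms = {
            "control": [flat_curve("c1", days, 100), flat_curve("c2", days, 140)],
            "treated": [flat_curve("t1", days, 100), flat_curve("t2", days, 140)],
        }
        res = compare_growth(TumorStudy(arms), "control")
        assert res.contrasts[0].mean_difference == 0.0
        assert res.contrasts[0].p_adjusted > 0.9

    def test_single_treated_arm_reduces_to_unadjusted_contrast(self):
        arms = synth.calibrated_tumor_arms(n_mice=8, noise_cv=0.3)
        study = synth.gen_tumor_study(arms, seed=21)
        res = compare_growth(study, "adjuvant")
        c = res.contrasts[0]
        # Dunnett with k = 1 is the plain two-sample pooled-t contrast
        assert c.p_adjusted == pytest.approx(c.p_unadjusted, abs=2e-3)

    def test_adjusted_p_never_below_unadjusted(self):
        model = synth.GrowthModel(noise_cv=0.4)
        arms = {
            "adjuvant": (6, model),
            "vx1": (6, synth.GrowthModel(arm_effect=0.8, noise_cv=0.4)),
            "vx2": (6, synth.GrowthModel(arm_effect=0.6, noise_cv=0.4)),
        }
        res = compare_growth(synth.gen_tumor_study(arms, seed=4), "adjuvant")
        assert len(res.contrasts) == 2
        for c in res.contrasts:
            assert c.p_adjusted >= c.p_unadjusted
            assert 0 <= c.p_adjusted <= 1

    def test_large_effect_detected_across_seeds(self):
        """A 0.3× growth-rate multiplier at n = 10/arm with low noise is
        detected by the adjusted contrast in nearly every replicate."""
        arms = {
            "adjuvant": (10, synth.GrowthModel(noise_cv=0.1)),
            "vaccine": (10, synth.GrowthModel(arm_effect=0.3, noise_cv=0.1)),
        }
        n_seeds = 200
        hits = 0
        for seed in range(n_seeds):
            study = synth.gen_tumor_study(arms, seed=seed, horizon_day=60)
            res = compare_growth(study, "adjuvant")
            # sanity lower bound: the unadjusted contrast must reject at
            # least as often as the adjusted one
            assert res.contrasts[0].p_unadjusted <= res.contrasts[0].p_adjusted
            if res.contrasts[0].p_adjusted < 0.05:
                hits += 1
        assert hits / n_seeds >= 0.95

    def test_errors(self):
        days = (0, 2)
        arms = {"a": [flat_curve("a1", days, 1), flat_curve("a2", days, 2)]}
        with pytest.raises(ValueError):
            compare_growth(TumorStudy(arms), "a")  # single arm
        arms["b"] = [flat_curve("b1", days, 1), flat_curve("b2", days, 2)]
        with pytest.raises(ValueError):
            compare_growth(TumorStudy(arms), "missing")


class TestToSurvival:
    def test_censored_at_horizon(self):
        study = TumorStudy({"a": [flat_curve("m1", (0, 50, 100), 500)]})
        rec = to_survival(study)[0]
        assert not rec.event
        assert rec.time == 115

    def test_linear_interpolation_of_crossing_day(self):
        curve = MouseCurve("m1", (38, 40, 42), (1500, 1800, 2200))
        rec = to_survival(TumorStudy({"a": [curve]}))[0]
        assert rec.event
        assert rec.time == pytest.approx(41.0)

    def test_threshold_is_inclusive(self):
        curve = MouseCurve("m1", (10, 12), (1500, 2000))
        rec = to_survival(TumorStudy({"a": [curve]}))[0]
        assert rec.event
        assert rec.time == 12

    def test_crossing_after_horizon_is_censored(self):
        curve = MouseCurve("m1", (110, 120), (1200, 2100))  # crosses at ~118.9
        rec = to_survival(TumorStudy({"a": [curve]}))[0]
        assert not rec.event
        assert rec.time == 115

    def test_noise_free_crossing_times_are_exact(self):
        """Deterministic exponential curves cross the threshold where the
        interpolated volume equals 2000, reproducibly through the pipeline."""
        arms = {"a": (3, synth.GrowthModel(baseline_volume=5.0,
                                           growth_rate=0.12, noise_cv=0.0))}
        study = synth.gen_tumor_study(arms, seed=0)
        records = to_survival(study)
        # crossing day solved from the piecewise-linear curve around
        # t* = ln(2000/5)/0.12 ≈ 49.93: grid points at 47 (v=1397.2) / 50 (v=2002.0)
        curve = study.arms["a"][0]
        i = next(j for j, v in enumerate(curve.volumes) if v >= 2000)
        d0, d1 = curve.days[i - 1], curve.days[i]
        v0, v1 = curve.volumes[i - 1], curve.volumes[i]
        expected = d0 + (2000 - v0) / (v1 - v0) * (d1 - d0)
        for rec in records:
            assert rec.event
            assert rec.time == pytest.approx(expected, abs=1e-9)

    def test_no_measurements_rejected(self):
        with pytest.raises(ValueError, match="no measurements"):
            MouseCurve("m1", (), ())


class TestKaplanMeier:
    def test_no_events_survival_is_one(self):
        recs = [SurvivalRecord(f"m{i}", "a", 115, False) for i in range(5)]
        km = km_estimate(recs)["a"]
        assert (km["survival"] == 1.0).all()

    def test_empirical_fraction_without_censoring(self):
        recs = [SurvivalRecord(f"m{i}", "a", 40 + i, True) for i in range(3)]
        recs += [SurvivalRecord(f"m{i+3}", "a", 115, False) for i in range(12)]
        assert survival_at(recs, 115)["a"] == pytest.approx(12 / 15)

    def test_staggered_fixture_matches_hand_computed_product_limit(self):
        recs = [
            SurvivalRecord("m1", "a", 2, True),
            SurvivalRecord("m2", "a", 4, False),
            SurvivalRecord("m3", "a", 5, True),
            SurvivalRecord("m4", "a", 7, True),
            SurvivalRecord("m5", "a", 8, False),
            SurvivalRecord("m6", "a", 10, True),
        ]
        km = km_estimate(recs)["a"]
        got = dict(zip(km["time"], km["survival"]))
        # product-limit by hand: S(2)=5/6, S(5)=5/6·3/4, S(7)=...·2/3, S(10)=0
        assert got[2.0] == pytest.approx(5 / 6)
        assert got[5.0] == pytest.approx(5 / 6 * 3 / 4)
        assert got[7.0] == pytest.approx(5 / 6 * 3 / 4 * 2 / 3)
        assert got[10.0] == pytest.approx(0.0)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([])


def fisher_oracle(a, b, c, d):
    """Exhaustive hypergeometric enumeration of the two-sided p-value."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)
    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestFisherExact:
    def test_strong_association(self):
        p = fisher_exact([[12, 3], [2, 13]])
        assert p == pytest.approx(fisher_oracle(12, 3, 2, 13), rel=1e-9)
        assert p == pytest.approx(6.8e-4, rel=0.05)

    def test_balanced_table(self):
        assert fisher_exact([[5, 5], [5, 5]]) == 1.0

    def test_degenerate_column(self):
        assert fisher_exact([[7, 0], [7, 0]]) == 1.0
        assert fisher_exact([[0, 0], [0, 0]]) == 1.0

    def test_validation(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, 2, 3], [4, 5, 6]])
        with pytest.raises(ValueError):
            fisher_exact([[1, -2], [3, 4]])
        with pytest.raises(ValueError):
            fisher_exact([[1.5, 2], [3, 4]])

    def test_matches_enumeration_on_moderate_margins(self):
        rng = np.random.default_rng(3)
        for _ in range(60):
            a, b, c, d = rng.integers(0, 9, size=4)
            assert fisher_exact([[a, b], [c, d]]) == pytest.approx(
                fisher_oracle(a, b, c, d), rel=1e-9, abs=1e-12)


class TestGroupSize:
    def test_monotone_in_effect_size_and_power(self):
        assert group_size(1.5) <= group_size(1.0)
        assert group_size(1.0, power=0.9) >= group_size(1.0, power=0.8)

    def test_matches_monte_carlo_power_within_one(self):
        d, alpha, power = 1.5, 0.05, 0.8
        n_analytic = group_size(d, alpha, power)
        rng = np.random.default_rng(12345)
        sims = 10_000

        def mc_power(n):
            x = rng.normal(0, 1, size=(sims, n))
            y = rng.normal(d, 1, size=(sims, n))
            p = stats.ttest_ind(x, y, axis=1, equal_var=True).pvalue
            return float(np.mean(p < alpha))

        n_mc = next(n for n in range(2, n_analytic + 5) if mc_power(n) >= power)
        assert abs(n_analytic - n_mc) <= 1

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            group_size(0.0)
        with pytest.raises(ValueError):
            group_size(1.0, power=1.5)
        with pytest.raises(ValueError):
            group_size(1e-6, max_n=50)


def test_read_measurements_round_trip(tmp_path):
    arms = synth.calibrated_tumor_arms(n_mice=3, noise_cv=0.2)
    study = synth.gen_tumor_study(arms, seed=9)
    df = synth.study_to_measurements_frame(study)
    path = tmp_path / "meas.csv"
    df.to_csv(path, index=False)
    back = read_measurements(path)
    assert set(back.arms) == {"adjuvant", "vaccine"}
    orig = study.to_frame().sort_values(["mouse", "day"]).reset_index(drop=True)
    rt = back.to_frame().sort_values(["mouse", "day"]).reset_index(drop=True)
    assert np.allclose(orig["volume"], rt["volume"])
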