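"""Two-sample Mendelian randomisation: harmonisation, estimators, outliers."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from transgwas import simulate
from transgwas.mr import (
    harmonize,
    ivw,
    modified_q_filter,
    mr_egger,
    run_mr,
    wald_ratio,
    weighted_median,
)
from conftest import make_instruments


def _exposure(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "effect_allele", "other_allele", "beta", "se"]
    )


class TestHarmonize:
    def test_opposite_orientation_flips_outcome(self):
        exp = _exposure([("1", 100, "A", "G", -0.1, 0.01)])
        out = _exposure([("1", 100, "G", "A", 0.05, 0.02)])
        instr = harmonize(exp, out)
        assert instr["beta_out"].iloc[0] == pytest.approx(-0.05)
        assert instr["beta_exp"].iloc[0] == pytest.approx(-0.1)

    def test_palindromic_variant_excluded(self):
        exp = _exposure(
            [("1", 100, "A", "T", -0.1, 0.01), ("1", 200, "C", "A", -0.1, 0.01)]
        )
        out = _exposure(
            [("1", 100, "A", "T", 0.05, 0.02), ("1", 200, "C", "A", 0.05, 0.02)]
        )
        instr = harmonize(exp, out)
        assert len(instr) == 1 and instr["pos"].iloc[0] == 200

    def test_exposure_oriented_to_trait_decreasing_allele(self):
        exp = _exposure([("1", 100, "A", "G", 0.1, 0.01)])
        out = _exposure([("1", 100, "A", "G", 0.05, 0.02)])
        instr = harmonize(exp, out)
        assert instr["beta_exp"].iloc[0] == pytest.approx(-0.1)
        assert instr["beta_out"].iloc[0] == pytest.approx(-0.05)
        assert instr["effect_allele"].iloc[0] == "G"

    def test_simulated_panel_counts_palindromes(self):
        cfg = simulate.SimConfig(seed=10)
        exposure, outcome, truth = simulate.simulate_mr(cfg)
        instr = harmonize(exposure, outcome)
        assert len(instr) == cfg.mr.n_instruments - cfg.mr.n_palindromic  # 94 - 3

    def test_no_shared_instruments_is_error(self):
        exp = _exposure([("1", 100, "A", "T", -0.1, 0.01)])
        out = _exposure([("1", 100, "A", "T", 0.05, 0.02)])
        with pytest.raises(ValueError, match="non-palindromic"):
            harmonize(exp, out)


class TestWaldRatio:
    def test_null_outcome_gives_zero(self):
        assert wald_ratio(0.1, 0.0, 0.05) == (0.0, pytest.approx(0.5))

    def test_hand_computed(self):
        est, se = wald_ratio(0.1, 0.2, 0.05)
        assert (est, se) == (pytest.approx(2.0), pytest.approx(0.5))

    def test_exposure_scaling_inverts_estimate(self):
        est1, _ = wald_ratio(0.1, 0.2, 0.05)
        est2, _ = wald_ratio(0.2, 0.2, 0.05)
        assert est2 == pytest.approx(est1 / 2)

    def test_zero_exposure_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.2, 0.05)


class TestIVW:
    def test_single_instrument_equals_wald_ratio(self, rng):
        instr = make_instruments(rng, n=1)
        fit = ivw(instr)
        est, se = wald_ratio(
            instr["beta_exp"].iloc[0], instr["beta_out"].iloc[0], instr["se_out"].iloc[0]
        )
        assert fit.estimate == pytest.approx(est) and fit.se == pytest.approx(se)

    def test_identical_ratios_recovered_exactly(self, rng):
        instr = make_instruments(rng, n=10, se_out=0.05)
        instr["beta_out"] = 0.7 * instr["beta_exp"]
        fit = ivw(instr)
        assert fit.estimate == pytest.approx(0.7, abs=1e-12)

    def test_estimate_invariant_to_common_se_rescaling(self, rng):
        instr = make_instruments(rng)
        fit1 = ivw(instr)
        instr2 = instr.assign(se_out=instr["se_out"] * 3)
        fit2 = ivw(instr2)
        assert fit2.estimate == pytest.approx(fit1.estimate, abs=1e-12)

    def test_recovers_planted_effect(self, rng):
        hits = 0
        for _ in range(100):
            fit = ivw(make_instruments(rng, theta=-0.3))
            hits += abs(fit.estimate + 0.3) <= 2 * fit.se
        assert hits >= 93

    def test_null_p_values_uniform(self, rng):
        ps = [ivw(make_instruments(rng, n=20, theta=0.0)).p for _ in range(400)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestModifiedQ:
    def test_qj_sums_to_global_cochran_q(self, rng):
        instr = make_instruments(rng)
        r = instr["beta_out"] / instr["beta_exp"]
        w = (instr["beta_exp"] / instr["se_out"]) ** 2
        mu = np.sum(w * r) / np.sum(w)
        q_global = float(np.sum(w * (r - mu) ** 2))
        qj = w * (r - mu) ** 2
        assert qj.sum() == pytest.approx(q_global, abs=1e-9)

    def test_planted_outlier_flagged(self, rng):
        detected = 0
        for _ in range(100):
            instr = make_instruments(rng, outlier=7)
            _, outliers, _ = modified_q_filter(instr)
            detected += int(8_000_000 in set(outliers["pos"]))
        assert detected >= 99

    def test_null_first_pass_flag_rate_near_alpha(self, rng):
        crit = stats.chi2.ppf(0.95, 1)
        rates = []
        for _ in range(100):
            instr = make_instruments(rng)
            r = instr["beta_out"] / instr["beta_exp"]
            w = (instr["beta_exp"] / instr["se_out"]) ** 2
            mu = np.sum(w * r) / np.sum(w)
            rates.append(np.mean(w * (r - mu) ** 2 > crit))
        assert abs(np.mean(rates) - 0.05) <= 0.015

    def test_too_few_instruments_rejected(self, rng):
        with pytest.raises(ValueError):
            modified_q_filter(make_instruments(rng, n=2))


class TestWeightedMedian:
    def test_symmetric_ratios_give_zero(self):
        instr = pd.DataFrame(
            {
                "chrom": "1",
                "pos": [1, 2, 3],
                "effect_allele": "A",
                "other_allele": "G",
                "beta_exp": [1.0, 1.0, 1.0],
                "se_exp": 0.01,
                "beta_out": [-1.0, 0.0, 1.0],
                "se_out": 0.1,
            }
        )
        fit = weighted_median(instr, rng=np.random.default_rng(0))
        assert fit.estimate == pytest.approx(0.0, abs=1e-12)

    def test_identical_ratios_returned_exactly(self, rng):
        instr = make_instruments(rng, n=7)
        instr["beta_out"] = -0.4 * instr["beta_exp"]
        fit = weighted_median(instr, rng=rng)
        assert fit.estimate == pytest.approx(-0.4, abs=1e-12)

    def test_breakdown_under_half_invalid_instruments(self, rng):
        # 49% of instruments are pleiotropic; the weighted median holds
        ests = []
        for _ in range(20):
            instr = make_instruments(rng, n=51, theta=0.5, se_out=0.02)
            bad = rng.choice(51, size=25, replace=False)
            instr.loc[bad, "beta_out"] += rng.uniform(0.3, 0.8, size=25)
            ests.append(weighted_median(instr, rng=rng).estimate)
        assert abs(np.mean(ests) - 0.5) <= 0.1


class TestEgger:
    def test_exact_line_through_origin_matches_ivw(self, rng):
        instr = make_instruments(rng, n=10)
        instr["beta_out"] = -0.25 * instr["beta_exp"]
        fit = mr_egger(instr)
        fit_ivw = ivw(instr)
        assert fit.estimate == pytest.approx(fit_ivw.estimate, abs=1e-9)
        assert fit.egger_intercept[0] == pytest.approx(0.0, abs=1e-12)

    def test_planted_directional_pleiotropy_in_intercept(self, rng):
        delta = 0.04
        ests = []
        for _ in range(50):
            instr = make_instruments(rng, n=60)
            # orient as Egger does before adding a constant pleiotropic offset
            sign = np.sign(instr["beta_exp"])
            instr["beta_out"] += delta * sign
            ests.append(mr_egger(instr).egger_intercept[0])
        assert np.mean(ests) == pytest.approx(delta, abs=0.01)

    def test_intercept_calibrated_under_no_pleiotropy(self, rng):
        covered = 0
        for _ in range(100):
            fit = mr_egger(make_instruments(rng))
            i0, se, _ = fit.egger_intercept
            covered += abs(i0) <= 2 * se
        assert covered >= 90

    def test_constant_exposure_rejected(self, rng):
        instr = make_instruments(rng, n=5)
        instr["beta_exp"] = 0.1
        with pytest.raises(ValueError, match="variation"):
            mr_egger(instr)


class TestRunMR:
    def test_bonferroni_threshold_for_12_traits(self, rng):
        components = {"A": make_instruments(rng), "B": make_instruments(rng)}
        results, _ = run_mr(components, outcome="ckd", n_traits=12, rng=rng)
        thr = 0.05 / 12
        assert f"{thr:.2g}" == "0.0042"
        for res in results:
            assert res.significant == (res.p < thr)

    def test_shared_effect_recovered_in_every_component(self, rng):
        components = {c: make_instruments(rng, theta=-0.3) for c in "ABC"}
        results, _ = run_mr(components, rng=rng)
        for res in results:
            if res.method == "ivw":
                assert abs(res.estimate + 0.3) <= 2 * res.se

    def test_outlier_union_removed_from_all_components(self, rng):
        instr_a = make_instruments(rng, outlier=5)
        instr_b = make_instruments(rng)  # same positions, no outlier here
        results, outliers = run_mr({"A": instr_a, "B": instr_b}, rng=rng)
        flagged_pos = 6_000_000
        flagged_in = set(outliers.loc[outliers["pos"] == flagged_pos, "component"])
        assert "A" in flagged_in
        for res in results:  # removed from B as well, wherever it was flagged
            assert ("1", flagged_pos) in res.outliers_removed
            assert res.n_instruments < 50
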