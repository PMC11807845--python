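"""The five MR estimators against closed-form and independent oracles."""

import subprocess

import numpy as np
import pytest

from mrscreen.estimators import (
    METHOD_ORDER,
    MethodMinimumError,
    ivw,
    mode_estimate,
    mr_egger,
    run_all_methods,
    wald_ratios,
    weighted_median,
)
from mrscreen.sumstats import harmonized_from_arrays


def _h(bx, by, sey, sex=None):
    bx = np.asarray(bx, dtype=float)
    sex = np.full(len(bx), 0.01) if sex is None else sex
    return harmonized_from_arrays(bx, sex, by, sey)


class TestWaldRatios:
    @pytest.mark.parametrize(
        "bx,by,sey,ratio,se,w",
        [
            (1.0, 0.5, 0.1, 0.5, 0.1, 100.0),
            (2.0, 1.2, 0.2, 0.6, 0.1, 100.0),
            (-1.0, -0.5, 0.1, 0.5, 0.1, 100.0),  # sign symmetry
        ],
    )
    def test_single_ratio_values(self, bx, by, sey, ratio, se, w):
        r = wald_ratios(_h([bx, 1.0], [by, 0.0], [sey, 1.0]))
        assert r["ratio"].iloc[0] == pytest.approx(ratio)
        assert r["ratio_se"].iloc[0] == pytest.approx(se)
        assert r["weight"].iloc[0] == pytest.approx(w)

    def test_zero_exposure_effect_excluded_with_reason(self):
        r = wald_ratios(_h([0.0, 1.0], [0.1, 0.2], [0.1, 0.1]))
        assert len(r) == 1
        assert r.attrs["excluded"] == ["snp0"]


class TestIVW:
    def test_two_ratio_closed_form(self):
        est = ivw(_h([1.0, 1.0], [0.5, 0.6], [0.1, 0.1]))
        assert est.beta == pytest.approx(0.55)
        assert est.se == pytest.approx(1.0 / np.sqrt(200.0), rel=1e-10)  # ~0.0707
        assert est.or_value == pytest.approx(np.exp(0.55), abs=1e-12)

    def test_identical_ratios_fixed_equals_random(self):
        h = _h([1.0, 2.0, 4.0], [0.3, 0.6, 1.2], [0.1, 0.2, 0.4])
        fixed = ivw(h, model="fixed")
        random = ivw(h, model="random")
        assert fixed.beta == pytest.approx(0.3)
        assert fixed.se == pytest.approx(random.se)  # Q=0: floor at 1 bites

    def test_single_instrument_rejected(self):
        with pytest.raises(MethodMinimumError):
            ivw(_h([1.0], [0.5], [0.1]))

    def test_random_effects_inflates_se_under_heterogeneity(self):
        h = _h([1.0] * 4, [0.1, 0.5, 0.9, 1.4], [0.05] * 4)
        assert ivw(h, model="random").se > ivw(h, model="fixed").se
        assert ivw(h, model="auto").se == ivw(h, model="random").se

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_zero_intercept_weighted_regression(self, seed):
        """IVW is algebraically the zero-intercept WLS slope of outcome on
        exposure effects with weights 1/se_outcome^2."""
        rng = np.random.default_rng(seed)
        k = rng.integers(3, 30)
        bx = rng.normal(0.1, 0.05, k)
        bx[np.abs(bx) < 1e-3] = 0.05
        sey = rng.uniform(0.01, 0.2, k)
        by = rng.normal(0.2 * bx, sey)
        est = ivw(_h(bx, by, sey), model="fixed")
        w = 1.0 / sey**2
        slope = np.sum(w * bx * by) / np.sum(w * bx**2)
        se = 1.0 / np.sqrt(np.sum(w * bx**2))
        assert est.beta == pytest.approx(slope, abs=1e-12)
        assert est.se == pytest.approx(se, abs=1e-12)


class TestEgger:
    def test_exact_line_recovered(self):
        est = mr_egger(_h([1.0, 2.0, 3.0], [0.3, 0.5, 0.7], [0.1, 0.1, 0.1]))
        assert est.beta == pytest.approx(0.2, abs=1e-12)
        assert est.egger_intercept == pytest.approx(0.1, abs=1e-12)

    def test_orientation_invariance(self):
        """Flipping the sign of any (bx, by) pair leaves the slope and
        |intercept| unchanged."""
        bx = np.array([1.0, 2.0, 3.0, 1.5])
        by = np.array([0.35, 0.52, 0.75, 0.40])
        sey = np.array([0.1, 0.12, 0.09, 0.11])
        base = mr_egger(_h(bx, by, sey))
        for j in range(4):
            bx2, by2 = bx.copy(), by.copy()
            bx2[j] *= -1
            by2[j] *= -1
            est = mr_egger(_h(bx2, by2, sey))
            assert est.beta == pytest.approx(base.beta, abs=1e-12)
            assert abs(est.egger_intercept) == pytest.approx(
                abs(base.egger_intercept), abs=1e-12)

    def test_matches_statsmodels_wls(self, rng):
        """Independent fit of the same weighted regression via statsmodels."""
        import statsmodels.api as sm

        k = 12
        bx = rng.uniform(0.05, 0.3, k)
        sey = rng.uniform(0.02, 0.1, k)
        by = rng.normal(0.15 * bx + 0.02, sey)
        est = mr_egger(_h(bx, by, sey))
        fit = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sey**2).fit()
        assert est.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert est.egger_intercept == pytest.approx(fit.params[0], abs=1e-10)
        # statsmodels scales coefficient SEs by the residual variance estimate
        # (no floor); compare after removing both scalings
        q = float(np.sum((1.0 / sey**2) * fit.resid**2))
        scale = max(1.0, np.sqrt(q / (k - 2)))
        sm_scale = np.sqrt(fit.scale)
        assert est.se / scale == pytest.approx(fit.bse[1] / sm_scale, abs=1e-10)

    def test_requires_three_instruments(self):
        with pytest.raises(MethodMinimumError):
            mr_egger(_h([1.0, 2.0], [0.3, 0.5], [0.1, 0.1]))


class TestWeightedMedian:
    def test_equal_weights_is_sample_median(self):
        est = weighted_median(_h([1.0] * 3, [0.4, 0.5, 0.9], [0.1] * 3), n_boot=50)
        assert est.beta == pytest.approx(0.5)

    def test_unequal_weights_interpolation(self):
        """Brute-force cumulative-weight oracle: weights (.1,.1,.8) over sorted
        ratios (0.4,0.5,0.9); midpoint cumulative weights are (.05,.15,.60) so
        the 0.5 crossing interpolates between 0.5 and 0.9."""
        sey = 1.0 / np.sqrt(np.array([1.0, 1.0, 8.0]))
        est = weighted_median(_h([1.0] * 3, [0.4, 0.5, 0.9], sey), n_boot=50)
        expected = 0.5 + (0.5 - 0.15) / (0.60 - 0.15) * (0.9 - 0.5)
        assert est.beta == pytest.approx(expected)
        assert expected == pytest.approx(0.5 + 0.35 / 0.45 * 0.4)

    def test_bootstrap_determinism(self):
        h = _h([1.0] * 5, [0.4, 0.5, 0.6, 0.7, 0.9], [0.1] * 5)
        a = weighted_median(h, n_boot=300, seed=11)
        b = weighted_median(h, n_boot=300, seed=11)
        c = weighted_median(h, n_boot=300, seed=12)
        assert a.se == b.se
        assert c.se != a.se
        assert c.se == pytest.approx(a.se, rel=0.3)  # Monte-Carlo tolerance

    def test_requires_three_instruments(self):
        with pytest.raises(MethodMinimumError):
            weighted_median(_h([1.0, 1.0], [0.4, 0.5], [0.1, 0.1]))


class TestMode:
    def test_majority_cluster_wins(self):
        h = _h([1.0] * 4, [0.5, 0.5, 0.5, 2.0], [0.1] * 4)
        est = mode_estimate(h, weighted=False, n_boot=0)
        assert est.beta == pytest.approx(0.5, abs=0.05)

    def test_degenerate_all_equal(self):
        h = _h([1.0] * 4, [0.3] * 4, [0.1] * 4)
        for bw in (0.5, 1.0, 2.0):
            est = mode_estimate(h, weighted=False, bandwidth_factor=bw, n_boot=0)
            assert est.beta == pytest.approx(0.3, abs=1e-9)

    def test_weighted_equals_simple_for_equal_weights(self):
        h = _h([1.0] * 5, [0.2, 0.3, 0.32, 0.4, 0.9], [0.1] * 5)
        simple = mode_estimate(h, weighted=False, n_boot=0)
        weighted = mode_estimate(h, weighted=True, n_boot=0)
        assert simple.beta == pytest.approx(weighted.beta, abs=1e-12)

    def test_bootstrap_se_positive_and_deterministic(self):
        h = _h([1.0] * 5, [0.2, 0.3, 0.32, 0.4, 0.9], [0.1] * 5)
        a = mode_estimate(h, weighted=True, n_boot=200, seed=4)
        b = mode_estimate(h, weighted=True, n_boot=200, seed=4)
        assert a.se == b.se > 0


class TestRunAll:
    def test_canonical_order_and_determinism(self):
        h = _h([1.0, 1.2, 0.8, 1.5, 0.9], [0.21, 0.25, 0.15, 0.31, 0.17],
               [0.05, 0.06, 0.05, 0.07, 0.05])
        a = run_all_methods(h, seed=9, n_boot=100)
        b = run_all_methods(h, seed=9, n_boot=100)
        assert [e.method for e in a] == list(METHOD_ORDER)
        assert [(e.beta, e.se, e.pvalue) for e in a] == [(e.beta, e.se, e.pvalue) for e in b]

    def test_failure_recorded_not_raised(self):
        h = _h([1.0, 1.2], [0.2, 0.25], [0.05, 0.06])  # enough for IVW only
        out = run_all_methods(h, seed=0, n_boot=10)
        assert [e.method for e in out] == list(METHOD_ORDER)
        assert out[0].error is None
        assert all(e.error is not None for e in out if e.method != "ivw")

    def test_or_is_exp_beta_everywhere(self):
        h = _h([1.0, 1.2, 0.8, 1.5], [0.21, 0.25, 0.15, 0.31], [0.05] * 4)
        for e in run_all_methods(h, seed=2, n_boot=50):
            assert e.or_value == pytest.approx(np.exp(e.beta), abs=1e-12)


@pytest.mark.parametrize("model", ["fixed"])
def test_ivw_matches_metafor_fixed_effect(model, tmp_path):
    """Cross-check the IVW meta-analysis against R's metafor package."""
    bx = np.array([1.0, 1.3, 0.7, 1.1, 0.9])
    sey = np.array([0.05, 0.08, 0.04, 0.06, 0.05])
    by = np.array([0.21, 0.30, 0.12, 0.24, 0.16])
    est = ivw(_h(bx, by, sey), model=model)
    ratios = by / bx
    ses = sey / np.abs(bx)
    script = tmp_path / "ivw.R"
    script.write_text(
        "suppressMessages(library(metafor))\n"
        f"yi <- c({','.join(map(str, ratios))})\n"
        f"sei <- c({','.join(map(str, ses))})\n"
        'fit <- rma(yi=yi, sei=sei, method="FE")\n'
        "cat(sprintf('%.12f %.12f\\n', fit$beta, fit$se))\n"
    )
    out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True,
                         timeout=120)
    assert out.returncode == 0, out.stderr
    beta_r, se_r = map(float, out.stdout.split())
    assert est.beta == pytest.approx(beta_r, abs=1e-9)
    assert est.se == pytest.approx(se_r, abs=1e-9)
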