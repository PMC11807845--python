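"""Causal-effect estimators for two-sample MR on harmonized summary statistics.

Five methods operate on per-variant Wald ratios (outcome effect over exposure
effect): inverse-variance-weighted meta-analysis (IVW, the primary estimator),
Egger regression with a free intercept, the weighted median, and kernel-based
simple/weighted mode estimators.  All estimates are on the log-odds scale for a
binary outcome; ``or_value = exp(beta)`` is the odds ratio.

Numerical conventions
---------------------
* Wald-ratio standard errors are first order: se_outcome / |beta_exposure|.
* IVW's random-effects variant scales the fixed-effect SE by
  max(1, sqrt(Q / (K - 1))) (multiplicative over-dispersion, floored at 1);
  ``model="auto"`` switches from fixed to random when Cochran's Q has p < 0.05.
* Egger rows are oriented so every exposure effect is non-negative before the
  weighted regression (weights 1/se_outcome^2); both coefficient SEs carry the
  analogous max(1, sqrt(Q'/(K-2))) scaling.
* Median/mode standard errors come from a parametric bootstrap: each ratio is
  resampled from Normal(ratio_j, ratio_se_j) and the estimator recomputed.
* Two-sided p-values use the standard normal reference by default; a Student-t
  reference is available for Egger.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sumstats import HarmonizedSet, InputError

Z95 = 1.959963984540054  # Phi^{-1}(0.975)

METHOD_ORDER = ("ivw", "egger", "simple_mode", "weighted_median", "weighted_mode")
METHOD_LABELS = {
    "ivw": "Inverse variance weighted",
    "egger": "MR Egger",
    "simple_mode": "Simple mode",
    "weighted_median": "Weighted median",
    "weighted_mode": "Weighted mode",
}
METHOD_MIN_SNPS = {
    "ivw": 2,
    "egger": 3,
    "simple_mode": 3,
    "weighted_median": 3,
    "weighted_mode": 3,
}


class MethodMinimumError(InputError):
    """Raised when a method receives fewer instruments than it requires."""


@dataclass
class MREstimate:
    """One method's causal estimate for an exposure-outcome pair."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    or_value: float
    pvalue: float
    n_snp: int
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    error: str | None = None

    @property
    def failed(self) -> bool:
        return self.error is not None


def _failure(method: str, n_snp: int, message: str) -> MREstimate:
    return MREstimate(
        method=method,
        beta=np.nan,
        se=np.nan,
        ci_low=np.nan,
        ci_high=np.nan,
        or_value=np.nan,
        pvalue=np.nan,
        n_snp=n_snp,
        error=message,
    )


def _finish(method: str, beta: float, se: float, n_snp: int, **extra) -> MREstimate:
    beta = float(beta)
    se = float(se)
    if se > 0 and np.isfinite(se):
        p = float(2.0 * sps.norm.sf(abs(beta) / se))
    else:
        p = np.nan
    return MREstimate(
        method=method,
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        or_value=float(np.exp(beta)),
        pvalue=p,
        n_snp=n_snp,
        **extra,
    )


def wald_ratios(h: HarmonizedSet) -> pd.DataFrame:
    """Per-variant Wald ratios with first-order SEs and inverse-variance weights.

    Rows with a zero exposure effect are excluded (the ratio is undefined) and
    listed in ``DataFrame.attrs['excluded']``.
    """
    t = h.table
    nonzero = t["beta_exposure"] != 0
    excluded = list(t.loc[~nonzero, "variant_id"])
    t = t.loc[nonzero]
    ratio = t["beta_outcome"].to_numpy() / t["beta_exposure"].to_numpy()
    ratio_se = t["se_outcome"].to_numpy() / np.abs(t["beta_exposure"].to_numpy())
    out = pd.DataFrame(
        {
            "variant_id": t["variant_id"].to_numpy(),
            "ratio": ratio,
            "ratio_se": ratio_se,
            "weight": 1.0 / ratio_se**2,
        }
    )
    out.attrs["excluded"] = excluded
    return out


def _ivw_from_arrays(ratio: np.ndarray, weight: np.ndarray, model: str) -> tuple:
    """Return (beta, se, q, df, q_pvalue, model_used)."""
    k = len(ratio)
    sw = weight.sum()
    beta = float(np.sum(weight * ratio) / sw)
    se_fixed = float(sw**-0.5)
    q = float(np.sum(weight * (ratio - beta) ** 2))
    df = k - 1
    q_p = float(sps.chi2.sf(q, df)) if df > 0 else np.nan
    if model == "auto":
        model_used = "random" if (df > 0 and q_p < 0.05) else "fixed"
    else:
        model_used = model
    scale = max(1.0, np.sqrt(q / df)) if (model_used == "random" and df > 0) else 1.0
    return beta, se_fixed * scale, q, df, q_p, model_used


def ivw(h: HarmonizedSet, model: str = "auto") -> MREstimate:
    """Inverse-variance-weighted meta-analysis of the Wald ratios.

    ``model`` is ``"fixed"``, ``"random"`` (multiplicative over-dispersion) or
    ``"auto"`` (fixed unless Cochran's Q has p < 0.05).  Requires >= 2
    instruments; a single Wald ratio is reported separately, never as IVW.
    """
    if model not in ("fixed", "random", "auto"):
        raise InputError(f"unknown IVW model {model!r}")
    r = wald_ratios(h)
    if len(r) < METHOD_MIN_SNPS["ivw"]:
        raise MethodMinimumError(f"IVW requires >= 2 instruments, got {len(r)}")
    beta, se, _, _, _, _ = _ivw_from_arrays(
        r["ratio"].to_numpy(), r["weight"].to_numpy(), model
    )
    return _finish("ivw", beta, se, len(r))


def _egger_fit(h: HarmonizedSet) -> dict:
    """Weighted Egger regression on rows oriented to beta_exposure >= 0."""
    t = h.table
    t = t.loc[t["beta_exposure"] != 0]
    k = len(t)
    if k < METHOD_MIN_SNPS["egger"]:
        raise MethodMinimumError(f"Egger requires >= 3 instruments, got {k}")
    sign = np.sign(t["beta_exposure"].to_numpy())
    x = t["beta_exposure"].to_numpy() * sign
    y = t["beta_outcome"].to_numpy() * sign
    w = 1.0 / t["se_outcome"].to_numpy() ** 2

    sw = w.sum()
    xbar = np.sum(w * x) / sw
    ybar = np.sum(w * y) / sw
    sxx = np.sum(w * (x - xbar) ** 2)
    if sxx <= 0:
        raise InputError("Egger regression is unidentified: no spread in exposure effects")
    slope = float(np.sum(w * (x - xbar) * (y - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)
    resid = y - intercept - slope * x
    q = float(np.sum(w * resid**2))
    df = k - 2
    scale = max(1.0, np.sqrt(q / df))
    slope_se = float(np.sqrt(1.0 / sxx)) * scale
    intercept_se = float(np.sqrt(1.0 / sw + xbar**2 / sxx)) * scale
    return {
        "slope": slope,
        "slope_se": slope_se,
        "intercept": intercept,
        "intercept_se": intercept_se,
        "q": q,
        "df": df,
        "n_snp": k,
    }


def mr_egger(h: HarmonizedSet, pvalue_dist: str = "normal") -> MREstimate:
    """Egger regression: the slope estimates the causal effect, the intercept
    the average directional pleiotropy.  ``pvalue_dist`` chooses the reference
    distribution for two-sided p-values (``"normal"`` or ``"t"`` with K-2 df).
    """
    fit = _egger_fit(h)
    est = _finish(
        "egger",
        fit["slope"],
        fit["slope_se"],
        fit["n_snp"],
        egger_intercept=fit["intercept"],
        egger_intercept_se=fit["intercept_se"],
        egger_intercept_p=float(
            2.0 * sps.norm.sf(abs(fit["intercept"]) / fit["intercept_se"])
        ),
    )
    if pvalue_dist == "t":
        df = fit["df"]
        est = replace(
            est,
            pvalue=float(2.0 * sps.t.sf(abs(est.beta) / est.se, df)),
            egger_intercept_p=float(
                2.0 * sps.t.sf(abs(fit["intercept"]) / fit["intercept_se"], df)
            ),
        )
    elif pvalue_dist != "normal":
        raise InputError(f"unknown pvalue_dist {pvalue_dist!r}")
    return est


def _weighted_median_point(ratio: np.ndarray, weight: np.ndarray) -> float:
    """Weighted median: the value where cumulative normalized weight reaches
    one half, linearly interpolating between order statistics at midpoint
    cumulative weights.  Reduces to the sample median for equal weights, odd K.
    """
    order = np.argsort(ratio, kind="mergesort")
    r = ratio[order]
    w = weight[order] / weight.sum()
    cum = np.cumsum(w) - 0.5 * w
    if 0.5 <= cum[0]:
        return float(r[0])
    if 0.5 >= cum[-1]:
        return float(r[-1])
    j = int(np.searchsorted(cum, 0.5))
    frac = (0.5 - cum[j - 1]) / (cum[j] - cum[j - 1])
    return float(r[j - 1] + frac * (r[j] - r[j - 1]))


def _weighted_median_rows(draws: np.ndarray, weight: np.ndarray) -> np.ndarray:
    """Row-wise weighted median of a (B, K) draw matrix (shared weights)."""
    order = np.argsort(draws, axis=1, kind="mergesort")
    r = np.take_along_axis(draws, order, axis=1)
    w = weight[order] / weight.sum()
    cum = np.cumsum(w, axis=1) - 0.5 * w
    out = np.empty(len(draws))
    for b in range(len(draws)):  # K is small; the sort above dominates
        cb, rb = cum[b], r[b]
        if 0.5 <= cb[0]:
            out[b] = rb[0]
        elif 0.5 >= cb[-1]:
            out[b] = rb[-1]
        else:
            j = int(np.searchsorted(cb, 0.5))
            frac = (0.5 - cb[j - 1]) / (cb[j] - cb[j - 1])
            out[b] = rb[j - 1] + frac * (rb[j] - rb[j - 1])
    return out


def weighted_median(
    h: HarmonizedSet, n_boot: int = 1000, seed: int | None = 0
) -> MREstimate:
    """Weighted-median estimator with a parametric-bootstrap standard error.

    Consistent as long as valid instruments carry more than half of the total
    inverse-variance weight.  ``n_boot = 0`` skips the bootstrap (SE is NaN).
    """
    r = wald_ratios(h)
    if len(r) < METHOD_MIN_SNPS["weighted_median"]:
        raise MethodMinimumError(
            f"weighted median requires >= 3 instruments, got {len(r)}"
        )
    ratio = r["ratio"].to_numpy()
    se = r["ratio_se"].to_numpy()
    weight = r["weight"].to_numpy()
    beta = _weighted_median_point(ratio, weight)
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        draws = rng.normal(ratio, se, size=(n_boot, len(ratio)))
        boot = _weighted_median_rows(draws, weight)
        se_hat = float(np.std(boot, ddof=1))
    else:
        se_hat = np.nan
    return _finish("weighted_median", beta, se_hat, len(r))


def _silverman_bandwidth(x: np.ndarray) -> float:
    """Modified Silverman rule: 0.9 * min(sd, IQR/1.34) * K^(-1/5)."""
    sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    q75, q25 = np.percentile(x, [75, 25])
    iqr = float(q75 - q25)
    spread = min(s for s in (sd, iqr / 1.34) if s > 0) if (sd > 0 or iqr > 0) else 0.0
    return 0.9 * spread * len(x) ** (-0.2)


def _mode_point(
    ratio: np.ndarray,
    weight: np.ndarray,
    bandwidth_factor: float,
    grid_size: int,
) -> float:
    """Argmax of a Gaussian-kernel weighted density of the ratios on a grid."""
    h = bandwidth_factor * _silverman_bandwidth(ratio)
    if h <= 0:  # degenerate: all ratios (numerically) identical
        return float(ratio[0])
    lo = ratio.min() - 3.0 * h
    hi = ratio.max() + 3.0 * h
    grid = np.linspace(lo, hi, grid_size)
    z = (grid[None, :] - ratio[:, None]) / h
    dens = np.einsum("k,kg->g", weight, np.exp(-0.5 * z**2))
    return float(grid[int(np.argmax(dens))])


def _mode_bootstrap(
    draws: np.ndarray,
    weight: np.ndarray,
    bandwidth_factor: float,
    grid_size: int,
    chunk: int = 64,
) -> np.ndarray:
    """Vectorized KDE-argmax over bootstrap draw rows, re-deriving the
    bandwidth per row (so degenerate point data stays well defined)."""
    b, k = draws.shape
    sd = np.std(draws, axis=1, ddof=1)
    q75, q25 = np.percentile(draws, [75, 25], axis=1)
    iqr = (q75 - q25) / 1.34
    spread = np.where(iqr > 0, np.minimum(sd, iqr), sd)
    hrow = bandwidth_factor * 0.9 * spread * k ** (-0.2)
    hrow = np.where(hrow > 0, hrow, 1e-12)
    out = np.empty(b)
    for start in range(0, b, chunk):
        d = draws[start : start + chunk]
        hh = hrow[start : start + chunk][:, None, None]
        lo = d.min(axis=1) - 3.0 * hrow[start : start + chunk]
        hi = d.max(axis=1) + 3.0 * hrow[start : start + chunk]
        grid = lo[:, None] + (hi - lo)[:, None] * np.linspace(0, 1, grid_size)[None, :]
        z = (grid[:, None, :] - d[:, :, None]) / hh
        dens = np.einsum("k,bkg->bg", weight, np.exp(-0.5 * z**2))
        idx = np.argmax(dens, axis=1)
        out[start : start + chunk] = grid[np.arange(len(d)), idx]
    return out


def mode_estimate(
    h: HarmonizedSet,
    weighted: bool,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = 0,
    grid_size: int = 512,
) -> MREstimate:
    """Mode-based estimator: the argmax of a kernel-smoothed density of the
    Wald ratios (equal kernel weights for the simple mode, inverse-variance
    weights for the weighted mode); SE by parametric bootstrap.
    """
    r = wald_ratios(h)
    method = "weighted_mode" if weighted else "simple_mode"
    if len(r) < METHOD_MIN_SNPS[method]:
        raise MethodMinimumError(f"{method} requires >= 3 instruments, got {len(r)}")
    ratio = r["ratio"].to_numpy()
    se = r["ratio_se"].to_numpy()
    kw = r["weight"].to_numpy() if weighted else np.ones(len(r))
    kw = kw / kw.sum()
    beta = _mode_point(ratio, kw, bandwidth_factor, grid_size)
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        draws = rng.normal(ratio, se, size=(n_boot, len(ratio)))
        boot = _mode_bootstrap(draws, kw, bandwidth_factor, grid_size)
        se_hat = float(np.std(boot, ddof=1))
    else:
        se_hat = np.nan
    return _finish(method, beta, se_hat, len(r))


def run_all_methods(
    h: HarmonizedSet,
    seed: int | None = 0,
    n_boot: int = 1000,
    ivw_model: str = "auto",
    bandwidth_factor: float = 1.0,
) -> list[MREstimate]:
    """All five estimators in canonical order (ivw, egger, simple_mode,
    weighted_median, weighted_mode), deterministic given ``seed``.

    A method failure (e.g. too few instruments after ratio exclusions) becomes
    a recorded failure entry with ``error`` set, never a silent omission.
    """
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    method_seeds = {
        m: int(s.generate_state(1)[0] % (2**31))
        for m, s in zip(METHOD_ORDER, ss.spawn(len(METHOD_ORDER)))
    }
    calls = {
        "ivw": lambda: ivw(h, model=ivw_model),
        "egger": lambda: mr_egger(h),
        "simple_mode": lambda: mode_estimate(
            h, weighted=False, bandwidth_factor=bandwidth_factor,
            n_boot=n_boot, seed=method_seeds["simple_mode"],
        ),
        "weighted_median": lambda: weighted_median(
            h, n_boot=n_boot, seed=method_seeds["weighted_median"]
        ),
        "weighted_mode": lambda: mode_estimate(
            h, weighted=True, bandwidth_factor=bandwidth_factor,
            n_boot=n_boot, seed=method_seeds["weighted_mode"],
        ),
    }
    out = []
    for method in METHOD_ORDER:
        try:
            out.append(calls[method]())
        except (InputError, ValueError) as exc:
            out.append(_failure(method, h.n_snp, str(exc)))
    return out


def estimates_table(
    estimates: Sequence[MREstimate],
    exposure_id: str = "",
    outcome: str = "",
    exposure: str = "",
) -> pd.DataFrame:
    """Export estimates as a delimited-friendly table mirroring the published
    screen layout (id.exposure, outcome, exposure, method, or) plus the full
    numeric columns."""
    rows = []
    for e in estimates:
        rows.append(
            {
                "id.exposure": exposure_id,
                "outcome": outcome,
                "exposure": exposure,
                "method": METHOD_LABELS.get(e.method, e.method),
                "or": e.or_value,
                "beta": e.beta,
                "se": e.se,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "pvalue": e.pvalue,
                "n_snp": e.n_snp,
                "error": e.error or "",
            }
        )
    return pd.DataFrame(rows)
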