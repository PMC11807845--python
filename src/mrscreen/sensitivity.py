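"""Heterogeneity, pleiotropy, and leave-one-out diagnostics for one
exposure-outcome pair.

* Cochran's Q (IVW form): weighted squared deviations of the Wald ratios about
  the fixed-effect pooled estimate; chi-square with K-1 df under homogeneity.
* Rucker's Q' (Egger form): weighted squared residuals about the Egger line;
  chi-square with K-2 df.
* Egger intercept test: a two-sided test of zero average directional
  pleiotropy; p < 0.05 flags horizontal pleiotropy.
* Leave-one-out: the IVW estimate recomputed dropping each instrument in turn;
  instability (a sign change, or a flip of nominal significance relative to
  the all-SNP estimate) flags single-variant dominance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .estimators import (
    METHOD_MIN_SNPS,
    MethodMinimumError,
    _egger_fit,
    _ivw_from_arrays,
    wald_ratios,
)
from .sumstats import HarmonizedSet, InputError


@dataclass
class HeterogeneityResult:
    method: str  # "ivw" or "egger"
    q: float
    df: int
    pvalue: float


@dataclass
class PleiotropyResult:
    intercept: float
    se: float
    pvalue: float

    @property
    def pleiotropic(self) -> bool:
        return self.pvalue < 0.05


@dataclass
class LeaveOneOutTable:
    rows: pd.DataFrame  # dropped_variant_id, ivw_beta, ivw_se, ivw_p
    all_snp_beta: float
    all_snp_se: float
    all_snp_p: float
    stable: bool


def cochran_q(h: HarmonizedSet, method: str = "ivw") -> HeterogeneityResult:
    """Heterogeneity statistic for the IVW fit (Q, df = K-1) or the Egger fit
    (Rucker's Q', df = K-2)."""
    if method == "ivw":
        r = wald_ratios(h)
        k = len(r)
        if k < 2:
            raise MethodMinimumError(f"Q for IVW requires >= 2 instruments, got {k}")
        _, _, q, df, q_p, _ = _ivw_from_arrays(
            r["ratio"].to_numpy(), r["weight"].to_numpy(), "fixed"
        )
        return HeterogeneityResult(method="ivw", q=q, df=df, pvalue=q_p)
    if method == "egger":
        fit = _egger_fit(h)
        q, df = fit["q"], fit["df"]
        return HeterogeneityResult(
            method="egger", q=q, df=df, pvalue=float(sps.chi2.sf(q, df))
        )
    raise InputError(f"unknown heterogeneity method {method!r}")


def egger_intercept_test(h: HarmonizedSet) -> PleiotropyResult:
    """Two-sided test of the Egger intercept (average directional pleiotropy)."""
    fit = _egger_fit(h)
    z = abs(fit["intercept"]) / fit["intercept_se"]
    return PleiotropyResult(
        intercept=fit["intercept"],
        se=fit["intercept_se"],
        pvalue=float(2.0 * sps.norm.sf(z)),
    )


def leave_one_out(
    h: HarmonizedSet,
    model: str = "auto",
    alpha: float = 0.05,
    require_significance_stability: bool = True,
) -> LeaveOneOutTable:
    """IVW re-estimated on every (K-1)-instrument subset.

    The stability flag is true when every subset estimate keeps the sign of the
    all-SNP estimate and (optionally) matches its nominal significance at
    ``alpha`` — an operational "no single SNP drives the result" criterion.
    """
    r = wald_ratios(h)
    k = len(r)
    if k < METHOD_MIN_SNPS["egger"]:
        raise MethodMinimumError(f"leave-one-out requires >= 3 instruments, got {k}")
    ratio = r["ratio"].to_numpy()
    weight = r["weight"].to_numpy()

    def _fit(mask: np.ndarray) -> tuple[float, float, float]:
        beta, se, _, _, _, _ = _ivw_from_arrays(ratio[mask], weight[mask], model)
        p = float(2.0 * sps.norm.sf(abs(beta) / se))
        return beta, se, p

    full_beta, full_se, full_p = _fit(np.ones(k, dtype=bool))
    rows = []
    for j in range(k):
        mask = np.ones(k, dtype=bool)
        mask[j] = False
        beta, se, p = _fit(mask)
        rows.append(
            {
                "dropped_variant_id": r["variant_id"].iloc[j],
                "ivw_beta": beta,
                "ivw_se": se,
                "ivw_p": p,
            }
        )
    table = pd.DataFrame(rows)

    same_sign = np.all(np.sign(table["ivw_beta"]) == np.sign(full_beta))
    stable = bool(same_sign)
    if require_significance_stability:
        full_sig = full_p < alpha
        stable = stable and bool(np.all((table["ivw_p"] < alpha) == full_sig))
    return LeaveOneOutTable(
        rows=table,
        all_snp_beta=full_beta,
        all_snp_se=full_se,
        all_snp_p=full_p,
        stable=stable,
    )


def loo_export(loo: LeaveOneOutTable) -> pd.DataFrame:
    """Leave-one-out table in per-SNP layout with a trailing "All" row."""
    all_row = pd.DataFrame(
        [
            {
                "dropped_variant_id": "All",
                "ivw_beta": loo.all_snp_beta,
                "ivw_se": loo.all_snp_se,
                "ivw_p": loo.all_snp_p,
            }
        ]
    )
    return pd.concat([loo.rows, all_row], ignore_index=True)
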