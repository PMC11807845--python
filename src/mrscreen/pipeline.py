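"""The forward/reverse screening pipeline over many exposures and one outcome.

For each exposure the screen runs: p-value instrument selection -> LD clumping
-> weak-instrument (F < 10) removal -> allele harmonization -> the five MR
estimators -> sensitivity diagnostics.  The retention decision then applies the
sequential rules, in this fixed order, stopping at the first failure:

1. ``ivw_not_significant`` — IVW p-value at or above ``ivw_screen_alpha``;
2. ``direction_inconsistent`` — the five odds ratios are not all on the same
   side of 1;
3. ``heterogeneity`` — Cochran's Q (IVW) or Rucker's Q' (Egger) p below
   ``q_alpha`` (configurable to IVW-only);
4. ``pleiotropy`` — Egger intercept p below ``intercept_alpha``;
5. ``loo_unstable`` — a leave-one-out subset estimate flips sign or nominal
   significance.

Exposures surviving all filters are retained and classified as risk (all five
odds ratios above 1) or protective (all below 1).  The reverse stage reuses
identical machinery with the stricter genome-wide instrument threshold
(P < 5e-8) and the outcome playing the exposure role.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .estimators import MREstimate, run_all_methods
from .instruments import LDMatrix, filter_weak_instruments, ld_clump, select_by_pvalue
from .sensitivity import (
    HeterogeneityResult,
    LeaveOneOutTable,
    PleiotropyResult,
    cochran_q,
    egger_intercept_test,
    leave_one_out,
)
from .sumstats import HarmonizedSet, InputError, SummaryStats, harmonize

REASON_IVW = "ivw_not_significant"
REASON_DIRECTION = "direction_inconsistent"
REASON_HETEROGENEITY = "heterogeneity"
REASON_PLEIOTROPY = "pleiotropy"
REASON_LOO = "loo_unstable"
REASON_TOO_FEW = "too_few_instruments"


@dataclass
class ScreeningConfig:
    """Thresholds and knobs for one screening run.

    ``het_rule`` is ``"either"`` (exclude when either the IVW Q or the Egger
    Q' is significant) or ``"ivw"`` (IVW Q only).  ``fdr`` switches the step-1
    screen from raw IVW p-values to Benjamini-Hochberg adjusted ones across
    the batch (off by default, matching the raw p < 0.05 usage).
    """

    exposure_p_threshold: float = 5e-6
    reverse_p_threshold: float = 5e-8
    clump_window_kb: float = 10_000.0
    clump_r2: float = 0.001
    ivw_screen_alpha: float = 0.05
    q_alpha: float = 0.05
    intercept_alpha: float = 0.05
    n_boot: int = 1000
    seed: int = 0
    f_min: float = 10.0
    min_instruments: int = 3
    het_rule: str = "either"
    ivw_model: str = "auto"
    loo_significance_stability: bool = True
    fdr: bool = False

    def __post_init__(self) -> None:
        for name in ("ivw_screen_alpha", "q_alpha", "intercept_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise InputError(f"{name}={v} outside (0, 1)")
        for name in ("exposure_p_threshold", "reverse_p_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise InputError(f"{name}={v} outside (0, 1)")
        if self.het_rule not in ("either", "ivw"):
            raise InputError(f"het_rule must be 'either' or 'ivw', got {self.het_rule!r}")


@dataclass
class ExposureScreenRecord:
    """Everything the screen computed for one exposure, plus the decision."""

    exposure_id: str
    decision: str  # "retained" or "excluded"
    reasons: list[str] = field(default_factory=list)
    effect_class: str = "none"  # "risk", "protective", or "none"
    estimates: list[MREstimate] = field(default_factory=list)
    heterogeneity: list[HeterogeneityResult] = field(default_factory=list)
    pleiotropy: PleiotropyResult | None = None
    loo: LeaveOneOutTable | None = None
    harmonized: HarmonizedSet | None = None
    selected_instruments: list[str] = field(default_factory=list)
    clumped_instruments: list[str] = field(default_factory=list)
    strength: pd.DataFrame | None = None
    reverse_null: bool | None = None

    @property
    def retained(self) -> bool:
        return self.decision == "retained"

    @property
    def ivw(self) -> MREstimate | None:
        for e in self.estimates:
            if e.method == "ivw":
                return e
        return None


def direction_consistent(estimates: Sequence[MREstimate]) -> bool:
    """True iff the five methods' odds ratios are all above 1 or all below 1.

    Any odds ratio exactly 1 (or unavailable) counts as inconsistent.
    """
    if len(estimates) != 5:
        raise InputError(f"expected exactly 5 estimates, got {len(estimates)}")
    ors = np.array([e.or_value for e in estimates], dtype=float)
    if np.any(~np.isfinite(ors)):
        return False
    return bool(np.all(ors > 1) or np.all(ors < 1))


def _exposure_seed(exposure_id: str, base_seed: int) -> int:
    """Stable per-exposure seed so batch results are order-independent."""
    return (zlib.crc32(exposure_id.encode()) ^ (base_seed & 0xFFFFFFFF)) % (2**31)


def screen_exposure(
    exposure: SummaryStats,
    outcome: SummaryStats,
    ld: LDMatrix | None,
    cfg: ScreeningConfig,
    p_threshold: float | None = None,
    seed: int | None = None,
) -> ExposureScreenRecord:
    """Run the full forward screen for a single exposure against the outcome.

    Too few instruments after the filters yields an excluded record with
    reason ``too_few_instruments`` rather than an exception, so batch runs
    always complete.
    """
    threshold = cfg.exposure_p_threshold if p_threshold is None else p_threshold
    seed = _exposure_seed(exposure.trait_id, cfg.seed) if seed is None else seed
    record = ExposureScreenRecord(exposure_id=exposure.trait_id, decision="excluded")

    selected = select_by_pvalue(exposure, threshold)
    record.selected_instruments = selected
    if len(selected) == 0:
        record.reasons = [REASON_TOO_FEW]
        return record
    clumped = (
        ld_clump(selected, ld, exposure, cfg.clump_window_kb, cfg.clump_r2)
        if ld is not None
        else selected
    )
    record.clumped_instruments = clumped
    strong, strength = filter_weak_instruments(exposure, clumped, cfg.f_min)
    record.strength = strength
    if len(strong) < cfg.min_instruments:
        record.reasons = [REASON_TOO_FEW]
        return record

    h = harmonize(exposure, outcome, strong)
    record.harmonized = h
    if h.n_snp < cfg.min_instruments:
        record.reasons = [REASON_TOO_FEW]
        return record

    record.estimates = run_all_methods(
        h, seed=seed, n_boot=cfg.n_boot, ivw_model=cfg.ivw_model
    )
    if any(e.failed for e in record.estimates):
        record.reasons = [REASON_TOO_FEW]
        return record
    record.heterogeneity = [cochran_q(h, "ivw"), cochran_q(h, "egger")]
    record.pleiotropy = egger_intercept_test(h)
    record.loo = leave_one_out(
        h,
        model=cfg.ivw_model,
        alpha=cfg.ivw_screen_alpha,
        require_significance_stability=cfg.loo_significance_stability,
    )

    ivw_est = record.ivw
    if not (ivw_est.pvalue < cfg.ivw_screen_alpha):
        record.reasons = [REASON_IVW]
    elif not direction_consistent(record.estimates):
        record.reasons = [REASON_DIRECTION]
    elif _heterogeneous(record.heterogeneity, cfg):
        record.reasons = [REASON_HETEROGENEITY]
    elif record.pleiotropy.pvalue < cfg.intercept_alpha:
        record.reasons = [REASON_PLEIOTROPY]
    elif not record.loo.stable:
        record.reasons = [REASON_LOO]
    else:
        record.decision = "retained"
        record.reasons = []
        ors = np.array([e.or_value for e in record.estimates])
        record.effect_class = "risk" if np.all(ors > 1) else "protective"
    return record


def _heterogeneous(results: Sequence[HeterogeneityResult], cfg: ScreeningConfig) -> bool:
    considered = [r for r in results if cfg.het_rule == "either" or r.method == "ivw"]
    return any(r.pvalue < cfg.q_alpha for r in considered)


def screen_many(
    exposures: Sequence[SummaryStats],
    outcome: SummaryStats,
    ld: LDMatrix | None,
    cfg: ScreeningConfig,
) -> list[ExposureScreenRecord]:
    """Screen every exposure independently against the outcome.

    Per-exposure seeds derive from a stable hash of the exposure id, so the
    output is reproducible and independent of exposure order.  With
    ``cfg.fdr`` enabled, step 1 uses Benjamini-Hochberg adjusted IVW p-values
    across the batch instead of raw ones.
    """
    if len(exposures) == 0:
        raise InputError("no exposures supplied")
    records = [screen_exposure(exp, outcome, ld, cfg) for exp in exposures]
    if cfg.fdr:
        _apply_fdr(records, cfg)
    return records


def _apply_fdr(records: list[ExposureScreenRecord], cfg: ScreeningConfig) -> None:
    """Re-evaluate step 1 with Benjamini-Hochberg adjusted IVW p-values."""
    testable = [r for r in records if r.ivw is not None and np.isfinite(r.ivw.pvalue)]
    if not testable:
        return
    pvals = np.array([r.ivw.pvalue for r in testable])
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 1.0
    for rank, idx in enumerate(reversed(order), start=0):
        i = m - rank
        running = min(running, pvals[idx] * m / i)
        adj[idx] = running
    for r, p_adj in zip(testable, adj):
        passed_raw = r.ivw.pvalue < cfg.ivw_screen_alpha
        passes_fdr = p_adj < cfg.ivw_screen_alpha
        if passed_raw and not passes_fdr and r.decision == "retained":
            r.decision = "excluded"
            r.reasons = [REASON_IVW]
            r.effect_class = "none"


def reverse_screen(
    outcome_as_exposure: SummaryStats,
    targets: Sequence[SummaryStats],
    ld: LDMatrix | None,
    cfg: ScreeningConfig,
) -> list[ExposureScreenRecord]:
    """Reverse MR: the outcome trait instruments (at the stricter threshold
    ``reverse_p_threshold``) are tested against each forward-retained target.

    A target is declared reverse-null when its IVW p-value is at or above
    0.05; heterogeneity/pleiotropy diagnostics are reported alongside.
    """
    if len(targets) == 0:
        raise InputError("no reverse targets supplied")
    records = []
    for target in targets:
        rec = screen_exposure(
            outcome_as_exposure,
            target,
            ld,
            cfg,
            p_threshold=cfg.reverse_p_threshold,
            seed=_exposure_seed(f"reverse:{target.trait_id}", cfg.seed),
        )
        rec.exposure_id = outcome_as_exposure.trait_id
        ivw_est = rec.ivw
        rec.reverse_null = bool(
            ivw_est is None
            or not np.isfinite(ivw_est.pvalue)
            or ivw_est.pvalue >= 0.05
        )
        records.append(rec)
    return records


def summary_table(records: Sequence[ExposureScreenRecord]) -> pd.DataFrame:
    """One row per exposure: decision, reason, effect class, IVW numbers."""
    rows = []
    for r in records:
        ivw_est = r.ivw
        rows.append(
            {
                "exposure_id": r.exposure_id,
                "decision": r.decision,
                "reason": r.reasons[0] if r.reasons else "",
                "effect_class": r.effect_class,
                "n_snp": r.harmonized.n_snp if r.harmonized is not None else 0,
                "ivw_or": ivw_est.or_value if ivw_est else np.nan,
                "ivw_p": ivw_est.pvalue if ivw_est else np.nan,
                "reverse_null": r.reverse_null,
            }
        )
    return pd.DataFrame(rows)
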