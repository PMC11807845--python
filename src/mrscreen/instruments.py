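"""Instrument selection: significance screen, LD clumping, and strength metrics.

Candidate instruments are the variants passing the exposure p-value screen
(P < 5e-6 by default for the forward direction).  Correlated candidates are
pruned by greedy clumping (keep the most significant variant, drop anything
within the window with r^2 above the cutoff), and per-variant strength is
quantified by the variance explained,

    R^2 = beta^2 / (beta^2 + SE^2 * N),

and the instrument F-statistic

    F = [(N - K - 1) / K] * R^2 / (1 - R^2),

with K = 1 for a single variant.  F < 10 flags a weak instrument.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .sumstats import InputError, SummaryStats

WEAK_F_THRESHOLD = 10.0


@dataclass
class LDMatrix:
    """Pairwise squared-correlation (r^2) matrix over an ordered variant set."""

    variant_ids: list[str]
    r2: np.ndarray
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        m = len(self.variant_ids)
        if self.r2.shape != (m, m):
            raise InputError(f"LD matrix shape {self.r2.shape} != ({m}, {m})")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise InputError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise InputError("LD matrix diagonal is not 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise InputError("LD r^2 values outside [0, 1]")
        self.r2 = np.clip(self.r2, 0.0, 1.0)
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def pair_r2(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    @classmethod
    def from_square_table(cls, path: str | Path, sep: str = "\t") -> "LDMatrix":
        """Load from a square delimited matrix with variant ids as header/index."""
        df = pd.read_csv(path, sep=sep, index_col=0)
        if list(df.index) != list(df.columns):
            raise InputError("LD table header and index disagree")
        return cls(variant_ids=list(df.columns), r2=df.to_numpy(dtype=float))

    @classmethod
    def from_panel(cls, dosages: pd.DataFrame) -> "LDMatrix":
        """Compute r^2 from a sample x variant dosage panel by squared Pearson r."""
        r = np.corrcoef(dosages.to_numpy(dtype=float), rowvar=False)
        r = np.nan_to_num(r, nan=0.0)
        np.fill_diagonal(r, 1.0)
        return cls(variant_ids=list(dosages.columns), r2=r**2)

    def to_square_table(self, path: str | Path, sep: str = "\t") -> None:
        pd.DataFrame(self.r2, index=self.variant_ids, columns=self.variant_ids).to_csv(
            path, sep=sep
        )


def _pvalue_order(stats: SummaryStats) -> pd.DataFrame:
    """Table sorted by ascending p, ties broken by (chromosome, position, id)."""
    return stats.table.sort_values(
        ["pvalue", "chromosome", "position", "variant_id"], kind="mergesort"
    )


def select_by_pvalue(stats: SummaryStats, threshold: float) -> list[str]:
    """Variant ids with p below ``threshold``, most significant first."""
    if not 0 < threshold <= 1:
        raise InputError(f"threshold {threshold} outside (0, 1]")
    ordered = _pvalue_order(stats)
    return list(ordered.loc[ordered["pvalue"] < threshold, "variant_id"])


def ld_clump(
    candidates: Sequence[str],
    ld: LDMatrix,
    stats: SummaryStats,
    window_kb: float = 10_000.0,
    r2_max: float = 0.001,
) -> list[str]:
    """Greedy LD clumping: sweep candidates by ascending p-value and keep a
    variant only if no previously kept variant on the same chromosome lies
    within ``window_kb`` and has r^2 above ``r2_max`` with it.

    The output is independent of the input candidate order because ordering is
    re-derived from the p-values; cross-chromosome pairs are never clumped.
    """
    if window_kb <= 0:
        raise InputError("window_kb must be positive")
    if not 0 <= r2_max <= 1:
        raise InputError("r2_max must lie in [0, 1]")
    missing = [c for c in candidates if c not in ld]
    if missing:
        raise InputError(f"candidates missing from LD matrix: {missing[:5]}")

    cand = set(candidates)
    ordered = _pvalue_order(stats)
    ordered = ordered[ordered["variant_id"].isin(cand)]
    window_bp = window_kb * 1000.0

    kept: list[str] = []
    kept_chrom: list[str] = []
    kept_pos: list[int] = []
    for row in ordered.itertuples(index=False):
        ok = True
        for kv, kc, kp in zip(kept, kept_chrom, kept_pos):
            if kc != row.chromosome:
                continue
            if abs(row.position - kp) > window_bp:
                continue
            if ld.pair_r2(row.variant_id, kv) > r2_max:
                ok = False
                break
        if ok:
            kept.append(row.variant_id)
            kept_chrom.append(row.chromosome)
            kept_pos.append(row.position)
    return kept


def variance_explained(beta, se, n):
    """Proportion of exposure variance explained by a variant.

    Uses R^2 = beta^2 / (beta^2 + SE^2 * N); the allele-frequency factor
    2*EAF*(1-EAF) cancels exactly in this form.  Vectorized over arrays.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(~(se > 0)):
        raise InputError("se must be positive")
    if np.any(~(n > 0)) or np.any(np.isnan(n)):
        raise InputError("sample size n missing or nonpositive")
    b2 = beta**2
    out = b2 / (b2 + se**2 * n)
    return float(out) if out.ndim == 0 else out


def f_statistic(r_squared, n, k: int = 1):
    """Instrument F-statistic, [(N-K-1)/K] * R^2 / (1-R^2).

    ``k`` is the number of instruments entering the formula: 1 for per-variant
    strength, or the instrument count for an aggregate F.
    """
    r_squared = np.asarray(r_squared, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(r_squared < 0) or np.any(r_squared >= 1):
        raise InputError("r_squared must lie in [0, 1)")
    if k < 1:
        raise InputError("k must be >= 1")
    if np.any(n <= k + 1):
        raise InputError(f"n must exceed k+1 = {k + 1}")
    out = (n - k - 1) / k * r_squared / (1 - r_squared)
    return float(out) if out.ndim == 0 else out


def instrument_strength(
    stats: SummaryStats, variant_ids: Sequence[str]
) -> pd.DataFrame:
    """Per-variant strength table: R^2, per-SNP F (K=1), and weak flag.

    The aggregate F over the whole set (K = number of instruments, pooled R^2)
    is attached as ``DataFrame.attrs['aggregate_f']``.
    """
    sub = stats.subset(variant_ids)
    n = sub["n"]
    if stats.default_n is not None:
        n = n.fillna(stats.default_n)
    r2 = variance_explained(sub["beta"].to_numpy(), sub["se"].to_numpy(), n.to_numpy())
    f = f_statistic(r2, n.to_numpy(), k=1)
    out = pd.DataFrame(
        {
            "variant_id": sub["variant_id"],
            "r_squared": r2,
            "f_stat": f,
            "k": 1,
            "weak": f < WEAK_F_THRESHOLD,
        }
    )
    k_all = len(sub)
    r2_total = min(float(np.sum(r2)), 1.0 - 1e-12)
    n_ref = float(np.min(n))
    if k_all >= 1 and n_ref > k_all + 1:
        out.attrs["aggregate_f"] = f_statistic(r2_total, n_ref, k=k_all)
        out.attrs["aggregate_k"] = k_all
    return out


def filter_weak_instruments(
    stats: SummaryStats, variant_ids: Sequence[str], f_min: float = WEAK_F_THRESHOLD
) -> tuple[list[str], pd.DataFrame]:
    """Drop variants with per-SNP F below ``f_min``; returns (kept, strength table)."""
    strength = instrument_strength(stats, variant_ids)
    kept = list(strength.loc[strength["f_stat"] >= f_min, "variant_id"])
    return kept, strength
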