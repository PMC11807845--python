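"""GWAS summary-statistics containers, delimited-text I/O, and allele harmonization.

A summary-statistics table holds one association record per variant: alleles,
effect-allele frequency (EAF), per-allele effect size ``beta``, its standard
error ``se``, the association p-value and the sample size ``n``.  Exposure and
outcome tables are joined onto a common effect-allele frame before any causal
estimation, with palindromic (A/T, C/G) variants removed because their strand
cannot be resolved from the alleles alone.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Canonical column order for summary-statistics files written by this package.
CANONICAL_COLUMNS = [
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
]

#: Columns that must be present (``eaf`` and ``n`` may be missing per record).
MANDATORY_COLUMNS = [c for c in CANONICAL_COLUMNS if c not in ("eaf", "n")]

VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# Closed enumeration of reasons a variant can be dropped during harmonization,
# so downstream filters are auditable.
DROP_PALINDROMIC = "palindromic"
DROP_MISSING = "missing_in_outcome"
DROP_MISMATCH = "allele_mismatch"
DROP_REASONS = (DROP_PALINDROMIC, DROP_MISSING, DROP_MISMATCH)


class ConfigurationError(ValueError):
    """A dialect/column-mapping problem (missing mandatory column, bad config)."""


class InputError(ValueError):
    """Invalid input data (empty file, empty instrument list, unknown variant)."""


@dataclass
class LoadReport:
    """Per-file accounting of rows kept versus dropped at load time."""

    n_total: int = 0
    n_kept: int = 0
    dropped: Counter = field(default_factory=Counter)

    @property
    def n_invalid(self) -> int:
        return self.n_total - self.n_kept


@dataclass
class SummaryStats:
    """One trait's GWAS summary statistics with a canonical-column table.

    ``table`` uses :data:`CANONICAL_COLUMNS`; ``variant_id`` values are unique.
    ``default_n`` fills in the sample size for records where ``n`` is missing.
    """

    trait_id: str
    table: pd.DataFrame
    default_n: int | None = None
    load_report: LoadReport | None = None

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.table.columns]
        if missing:
            raise ConfigurationError(f"summary statistics missing columns: {missing}")
        if self.table["variant_id"].duplicated().any():
            dups = self.table.loc[self.table["variant_id"].duplicated(), "variant_id"]
            raise InputError(f"duplicate variant ids: {sorted(set(dups))[:5]}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def variant_ids(self) -> pd.Series:
        return self.table["variant_id"]

    def effective_n(self) -> pd.Series:
        """Sample size per record, falling back to ``default_n`` where missing."""
        n = self.table["n"]
        if self.default_n is not None:
            n = n.fillna(self.default_n)
        return n

    def subset(self, variant_ids: Iterable[str]) -> pd.DataFrame:
        wanted = pd.Index(list(variant_ids), name="variant_id")
        sub = self.table.set_index("variant_id").loc[wanted].reset_index()
        return sub


@dataclass
class HarmonizedSet:
    """Exposure/outcome effect pairs on the exposure's effect-allele frame.

    ``table`` has one row per retained instrument with columns ``variant_id``,
    ``beta_exposure``, ``se_exposure``, ``beta_outcome``, ``se_outcome``,
    ``eaf_exposure``.  ``dropped`` lists ``(variant_id, reason)`` pairs for
    instruments that could not be carried through.
    """

    exposure_id: str
    outcome_id: str
    table: pd.DataFrame
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_snp(self) -> int:
        return len(self.table)


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, LoadReport]:
    """Drop rows violating record invariants, counting each reason."""
    report = LoadReport(n_total=len(df))
    reasons = {
        "bad_allele": ~(
            df["effect_allele"].isin(VALID_ALLELES)
            & df["other_allele"].isin(VALID_ALLELES)
        ),
        "same_alleles": df["effect_allele"] == df["other_allele"],
        "nonpositive_se": ~(df["se"] > 0),
        "bad_eaf": df["eaf"].notna() & ~df["eaf"].between(0.0, 1.0),
        "bad_pvalue": ~((df["pvalue"] > 0) & (df["pvalue"] <= 1)),
        "bad_position": ~(df["position"] >= 1),
        "nonfinite_beta": pd.Series(
            ~np.isfinite(df["beta"].to_numpy(dtype=float)), index=df.index
        ),
        "bad_n": df["n"].notna() & ~(df["n"] > 0),
    }
    bad = pd.Series(False, index=df.index)
    for reason, mask in reasons.items():
        newly = mask & ~bad
        if newly.any():
            report.dropped[reason] += int(newly.sum())
        bad |= mask.fillna(True)
    kept = df.loc[~bad].copy()
    report.n_kept = len(kept)
    return kept, report


def load_dialect(source: str | Path | Mapping[str, str]) -> dict[str, str]:
    """Return a ``{source column -> canonical column}`` mapping.

    ``source`` may already be a mapping, or a path to a YAML file holding one.
    """
    if isinstance(source, Mapping):
        mapping = dict(source)
    else:
        with open(source) as fh:
            mapping = yaml.safe_load(fh)
        if not isinstance(mapping, Mapping):
            raise ConfigurationError(f"dialect file {source} is not a mapping")
        mapping = dict(mapping)
    unknown = [v for v in mapping.values() if v not in CANONICAL_COLUMNS]
    if unknown:
        raise ConfigurationError(f"dialect maps onto unknown canonical names: {unknown}")
    return mapping


def read_sumstats(
    path: str | Path,
    dialect: str | Path | Mapping[str, str] | None = None,
    trait_id: str | None = None,
    sep: str = "\t",
    default_n: int | None = None,
) -> SummaryStats:
    """Read a delimited summary-statistics file into a :class:`SummaryStats`.

    ``dialect`` maps foreign header names (e.g. SNP/CHR/BP/A1/A2/FRQ/BETA/SE/P/N
    exports) onto the canonical names; rows violating record invariants are
    dropped and tallied in ``load_report``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep)
    if dialect is not None:
        df = df.rename(columns=load_dialect(dialect))
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path.name}: missing mandatory columns {missing}; "
            "provide a dialect mapping if the file uses foreign headers"
        )
    for optional in ("eaf", "n"):
        if optional not in df.columns:
            df[optional] = np.nan
    if len(df) == 0:
        raise InputError(f"{path.name}: no data rows")
    df = df[CANONICAL_COLUMNS]
    df = df.astype(
        {
            "variant_id": str,
            "chromosome": str,
            "position": "int64",
            "effect_allele": str,
            "other_allele": str,
            "eaf": float,
            "beta": float,
            "se": float,
            "pvalue": float,
            "n": float,
        }
    )
    df["effect_allele"] = df["effect_allele"].str.upper()
    df["other_allele"] = df["other_allele"].str.upper()
    kept, report = _validate_rows(df)
    return SummaryStats(
        trait_id=trait_id or path.stem,
        table=kept,
        default_n=default_n,
        load_report=report,
    )


def write_sumstats(stats: SummaryStats, path: str | Path) -> None:
    """Write canonical-column tab-delimited text; round-trips field-for-field."""
    df = stats.table[CANONICAL_COLUMNS]
    df.to_csv(path, sep="\t", index=False)


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True for A/T and C/G pairs, whose strand is ambiguous from alleles alone."""
    return _COMPLEMENT.get(effect_allele) == other_allele


def _complement_pair(ea: str, oa: str) -> tuple[str, str]:
    return _COMPLEMENT[ea], _COMPLEMENT[oa]


def harmonize(
    exposure: SummaryStats,
    outcome: SummaryStats,
    instrument_ids: Sequence[str],
) -> HarmonizedSet:
    """Align outcome effects onto the exposure's effect-allele frame.

    For each instrument present in both traits: matching allele pairs are copied
    unchanged; swapped effect/other alleles flip the sign of the outcome beta
    (and EAF becomes 1-EAF); complementary alleles are strand-flipped first and
    then the same rules apply.  Palindromic variants are dropped unconditionally
    (no frequency-based rescue), as are variants missing from the outcome or
    with irreconcilable alleles.
    """
    if len(instrument_ids) == 0:
        raise InputError("instrument_ids is empty")
    exp = exposure.table.set_index("variant_id")
    missing_in_exposure = [v for v in instrument_ids if v not in exp.index]
    if missing_in_exposure:
        raise InputError(
            f"instrument ids absent from exposure {exposure.trait_id}: "
            f"{missing_in_exposure[:5]}"
        )
    out = outcome.table.set_index("variant_id")

    rows = []
    dropped: list[tuple[str, str]] = []
    for vid in instrument_ids:
        e = exp.loc[vid]
        ea, oa = e["effect_allele"], e["other_allele"]
        if is_palindromic(ea, oa):
            dropped.append((vid, DROP_PALINDROMIC))
            continue
        if vid not in out.index:
            dropped.append((vid, DROP_MISSING))
            continue
        o = out.loc[vid]
        o_ea, o_oa = o["effect_allele"], o["other_allele"]
        if (o["chromosome"], o["position"]) != (e["chromosome"], e["position"]):
            # GWAS builds differ between consortia; id-matching stays authoritative.
            logger.info(
                "variant %s: chromosome/position disagree between %s and %s",
                vid,
                exposure.trait_id,
                outcome.trait_id,
            )
        if (o_ea, o_oa) == (ea, oa):
            beta_out = o["beta"]
        elif (o_ea, o_oa) == (oa, ea):
            beta_out = -o["beta"]
        elif _complement_pair(o_ea, o_oa) == (ea, oa):
            beta_out = o["beta"]
        elif _complement_pair(o_ea, o_oa) == (oa, ea):
            beta_out = -o["beta"]
        else:
            dropped.append((vid, DROP_MISMATCH))
            continue
        rows.append(
            {
                "variant_id": vid,
                "beta_exposure": float(e["beta"]),
                "se_exposure": float(e["se"]),
                "beta_outcome": float(beta_out),
                "se_outcome": float(o["se"]),
                "eaf_exposure": float(e["eaf"]),
            }
        )

    table = pd.DataFrame(
        rows,
        columns=[
            "variant_id",
            "beta_exposure",
            "se_exposure",
            "beta_outcome",
            "se_outcome",
            "eaf_exposure",
        ],
    )
    return HarmonizedSet(
        exposure_id=exposure.trait_id,
        outcome_id=outcome.trait_id,
        table=table,
        dropped=dropped,
    )


def harmonized_from_arrays(
    beta_exposure,
    se_exposure,
    beta_outcome,
    se_outcome,
    variant_ids=None,
    exposure_id: str = "exposure",
    outcome_id: str = "outcome",
    eaf_exposure=None,
) -> HarmonizedSet:
    """Build a :class:`HarmonizedSet` directly from aligned effect arrays."""
    bx = np.asarray(beta_exposure, dtype=float)
    k = len(bx)
    if variant_ids is None:
        variant_ids = [f"snp{i}" for i in range(k)]
    table = pd.DataFrame(
        {
            "variant_id": list(variant_ids),
            "beta_exposure": bx,
            "se_exposure": np.asarray(se_exposure, dtype=float),
            "beta_outcome": np.asarray(beta_outcome, dtype=float),
            "se_outcome": np.asarray(se_outcome, dtype=float),
            "eaf_exposure": (
                np.full(k, np.nan)
                if eaf_exposure is None
                else np.asarray(eaf_exposure, dtype=float)
            ),
        }
    )
    return HarmonizedSet(exposure_id=exposure_id, outcome_id=outcome_id, table=table)
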