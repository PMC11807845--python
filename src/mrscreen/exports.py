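"""Tabular exports of screening results: the master five-method odds-ratio
table, forest/scatter/leave-one-out plot data, and the all-exposure circle-plot
p-value table.  Only the data behind the figures is produced, not graphics."""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .estimators import METHOD_LABELS, METHOD_ORDER, estimates_table
from .pipeline import ExposureScreenRecord
from .sensitivity import loo_export


def master_table(
    records: Sequence[ExposureScreenRecord], outcome_name: str = ""
) -> pd.DataFrame:
    """Five rows per screened exposure (id.exposure, outcome, exposure, method,
    or, ...), mirroring the published screen layout."""
    parts = []
    for r in records:
        if not r.estimates:
            continue
        parts.append(
            estimates_table(
                r.estimates,
                exposure_id=r.exposure_id,
                outcome=outcome_name,
                exposure=r.exposure_id,
            )
        )
    if not parts:
        return pd.DataFrame()
    return pd.concat(parts, ignore_index=True)


def forest_data(records: Sequence[ExposureScreenRecord]) -> pd.DataFrame:
    """Per exposure and method: OR with 95% CI bounds, for forest plots."""
    rows = []
    for r in records:
        for e in r.estimates:
            rows.append(
                {
                    "exposure_id": r.exposure_id,
                    "method": METHOD_LABELS.get(e.method, e.method),
                    "or": e.or_value,
                    "or_low": float(np.exp(e.ci_low)),
                    "or_high": float(np.exp(e.ci_high)),
                    "pvalue": e.pvalue,
                    "n_snp": e.n_snp,
                }
            )
    return pd.DataFrame(rows)


def scatter_data(record: ExposureScreenRecord) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-SNP effects and per-method fitted lines for one exposure.

    Returns ``(points, lines)``: points carry (beta_exposure, se_exposure,
    beta_outcome, se_outcome) per instrument; lines carry slope/intercept per
    method (intercept 0 except for Egger).
    """
    if record.harmonized is None:
        raise ValueError(f"{record.exposure_id}: no harmonized instruments")
    points = record.harmonized.table.copy()
    rows = []
    for e in record.estimates:
        rows.append(
            {
                "method": METHOD_LABELS.get(e.method, e.method),
                "slope": e.beta,
                "intercept": e.egger_intercept if e.method == "egger" else 0.0,
            }
        )
    return points, pd.DataFrame(rows)


def loo_data(record: ExposureScreenRecord) -> pd.DataFrame:
    """Leave-one-out table (one row per omitted variant plus an "All" row)."""
    if record.loo is None:
        raise ValueError(f"{record.exposure_id}: no leave-one-out analysis")
    out = loo_export(record.loo)
    out.insert(0, "exposure_id", record.exposure_id)
    return out


def circle_data(records: Sequence[ExposureScreenRecord]) -> pd.DataFrame:
    """Per-method p-values across all exposures (circle-plot layout): one row
    per exposure, one column per method, NaN where a method did not run."""
    rows = []
    for r in records:
        row = {"exposure_id": r.exposure_id}
        by_method = {e.method: e.pvalue for e in r.estimates}
        for m in METHOD_ORDER:
            row[f"p_{m}"] = by_method.get(m, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def write_screen_outputs(
    records: Sequence[ExposureScreenRecord],
    out_dir: str | Path,
    outcome_name: str = "",
) -> None:
    """Write the master table, circle/forest data, and per-exposure scatter and
    leave-one-out tables for retained exposures under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master_table(records, outcome_name).to_csv(
        out_dir / "master_table.tsv", sep="\t", index=False
    )
    circle_data(records).to_csv(out_dir / "circle_data.tsv", sep="\t", index=False)
    forest_data(records).to_csv(out_dir / "forest_data.tsv", sep="\t", index=False)
    for r in records:
        if not r.retained or r.harmonized is None:
            continue
        points, lines = scatter_data(r)
        points.to_csv(out_dir / f"scatter_points_{r.exposure_id}.tsv", sep="\t", index=False)
        lines.to_csv(out_dir / f"scatter_lines_{r.exposure_id}.tsv", sep="\t", index=False)
        loo_data(r).to_csv(out_dir / f"loo_{r.exposure_id}.tsv", sep="\t", index=False)


def load_published_screen() -> pd.DataFrame:
    """The published five-method odds-ratio table for the 13 white-matter
    connectivity exposures that passed the initial IVW screen against
    Alzheimer's disease (GWAS Catalog exposure accessions; typed from the
    published report).  Columns: id.exposure, outcome, exposure, method, or."""
    with resources.files("mrscreen.data").joinpath("published_or_screen.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
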