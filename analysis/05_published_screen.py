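#!/usr/bin/env python
"""The odds-ratio direction-consistency rule on the published screen table.

Thirteen white-matter connectivity exposures passed the initial IVW screen
against Alzheimer's disease in the published study this package models.  This
driver applies the five-method direction-consistency rule to their published
odds ratios and writes the verdicts under results/published/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mrscreen.estimators import MREstimate
from mrscreen.exports import load_published_screen
from mrscreen.pipeline import direction_consistent

ROOT = Path(__file__).resolve().parent.parent / "results" / "published"

METHOD_BY_LABEL = {
    "Inverse variance weighted": "ivw",
    "MR Egger": "egger",
    "Simple mode": "simple_mode",
    "Weighted median": "weighted_median",
    "Weighted mode": "weighted_mode",
}


def main() -> None:
    table = load_published_screen()
    rows = []
    for exposure_id, group in table.groupby("id.exposure"):
        estimates = []
        for _, row in group.iterrows():
            o = float(row["or"])
            estimates.append(MREstimate(
                method=METHOD_BY_LABEL[row["method"]], beta=float(np.log(o)), se=0.1,
                ci_low=0.0, ci_high=1.0, or_value=o, pvalue=0.01, n_snp=10))
        consistent = direction_consistent(estimates)
        ors = group["or"].astype(float)
        rows.append({
            "id.exposure": exposure_id,
            "exposure": group["exposure"].iloc[0],
            "direction_consistent": consistent,
            "effect_class": ("risk" if consistent and (ors > 1).all()
                             else "protective" if consistent else "excluded"),
        })
    verdicts = pd.DataFrame(rows)
    ROOT.mkdir(parents=True, exist_ok=True)
    verdicts.to_csv(ROOT / "direction_verdicts.tsv", sep="\t", index=False)
    n_ok = int(verdicts["direction_consistent"].sum())
    print(verdicts[["id.exposure", "direction_consistent", "effect_class"]]
          .to_string(index=False))
    print(f"\n{len(verdicts)} candidates screened -> {n_ok} direction-consistent "
          f"connections retained, {len(verdicts) - n_ok} excluded")
    risk = verdicts[verdicts["effect_class"] == "risk"]["id.exposure"].tolist()
    print(f"risk factors (all five ORs > 1): {risk}")


if __name__ == "__main__":
    main()
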