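#!/usr/bin/env python
"""Generate a demonstration screening cohort and write it to disk.

Simulates a batch of connectivity-style exposure GWAS sharing one variant
grid, one binary-outcome GWAS (with allele-order perturbations and palindromic
variants), and one LD panel, then writes everything in the package's canonical
tab-delimited formats under results/cohort/.  Four exposures carry planted
causal effects (one risk, three protective); the rest are null.
"""

from pathlib import Path

import yaml

from mrscreen.simulate import simulate_cohort
from mrscreen.sumstats import write_sumstats

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 20_260_101


def main() -> None:
    exposures, outcome, ld, truth = simulate_cohort(
        n_exposures=24, n_risk=1, n_protective=3, k_instruments=10, seed=SEED)
    exp_dir = OUT / "exposures"
    exp_dir.mkdir(parents=True, exist_ok=True)
    for stats in exposures:
        write_sumstats(stats, exp_dir / f"{stats.trait_id}.tsv")
    write_sumstats(outcome, OUT / "outcome.tsv")
    ld.to_square_table(OUT / "ld.tsv")
    with open(OUT / "truth.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "theta_by_exposure": {k: float(v) for k, v in
                                      truth.theta_by_exposure.items()},
                "instruments_by_exposure": truth.instruments_by_exposure,
            },
            fh,
        )
    planted = truth.planted()
    print(f"wrote {len(exposures)} exposure GWAS ({len(outcome.table)} variants each), "
          f"one outcome GWAS and the LD panel to {OUT}")
    print(f"planted effects: {planted}")


if __name__ == "__main__":
    main()
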