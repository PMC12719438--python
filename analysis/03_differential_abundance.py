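#!/usr/bin/env python
"""Covariate-adjusted differential abundance per cohort and pooled.

Runs the bias-corrected log-linear model per cohort (adjusting for the
covariates that cohort reports) and on the pooled data (adjusting for cohort
of origin), with Holm FWER control.  The generator plants a
*Peptoniphilus*-like enriched genus; the pooled analysis should recover it.
"""

import argparse
from pathlib import Path

import pandas as pd

import vmec

ROOT = Path(__file__).resolve().parents[1]
ADJUST = ("age", "bmi", "ethnicity")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    study = vmec.simulate_multicohort(
        vmec.SimulationConfig(seed=args.seed, sequencing_depth_mean=5000)
    )
    (ROOT / "results").mkdir(exist_ok=True)

    for c in study.cohorts:
        genus = vmec.aggregate_to_genus(c.counts, c.taxonomy)
        design = pd.DataFrame({"diagnosis": c.labels})
        for cov in ADJUST:
            if cov in c.available_covariates:
                design[cov] = c.covariates[cov]
        res = vmec.fit_bias_corrected_da(genus, design)
        res.to_tsv(ROOT / "results" / f"da_{c.cohort_id}.tsv")
        sig = res.significant(0.05)
        print(f"{c.cohort_id:10s} adjusted for {list(design.columns[1:])}: "
              f"{len(sig)} genera at Holm alpha=0.05; "
              f"Peptoniphilus p_holm={res.table.loc['Peptoniphilus', 'p_holm']:.2e}")

    counts, labels, _, batch = study.pooled("all")
    genus = vmec.aggregate_to_genus(counts, study.taxonomy)
    pooled = vmec.fit_bias_corrected_da(
        genus, pd.DataFrame({"diagnosis": labels, "cohort": batch})
    )
    pooled.to_tsv(ROOT / "results" / "da_pooled.tsv")
    top = pooled.table.sort_values("p_holm").head(5)
    print("\npooled (cohort-adjusted) top genera:")
    print(top[["lfc", "se", "p_holm"]].to_string())
    print("\nThe planted Peptoniphilus-like enrichment is the expected top hit.")


if __name__ == "__main__":
    main()
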