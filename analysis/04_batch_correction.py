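#!/usr/bin/env python
"""Empirical-Bayes batch correction of pooled CLR features.

Quantifies, by marginal PERMANOVA R2 on Euclidean distances of CLR
features, how much cohort-of-origin signal the adjustment removes and how
much disease signal it preserves (disease label protected in the design).
"""

import argparse
import json
from pathlib import Path

import pandas as pd
from scipy.spatial.distance import pdist, squareform

import vmec

ROOT = Path(__file__).resolve().parents[1]


def r2_of(values, series, name, seed):
    dm = vmec.DistanceMatrix(list(values.index), squareform(pdist(values)), "bray_curtis")
    res = vmec.permanova_marginal(
        dm, pd.DataFrame({name: series}, index=values.index), n_perm=199, seed=seed
    )
    return res.terms[name].r2


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    study = vmec.simulate_multicohort(
        vmec.SimulationConfig(seed=args.seed, sequencing_depth_mean=5000)
    )
    counts, labels, _, batch = study.pooled("training")
    fm = vmec.build_feature_matrix(counts, study.taxonomy, labels)
    adjusted, model = vmec.fit_apply_combat(fm.values, batch, protect=labels)

    out = {
        "batch_r2_pre": r2_of(fm.values, batch, "cohort", args.seed),
        "batch_r2_post": r2_of(adjusted, batch, "cohort", args.seed),
        "disease_r2_pre": r2_of(fm.values, labels, "dx", args.seed),
        "disease_r2_post": r2_of(adjusted, labels, "dx", args.seed),
    }
    (ROOT / "results").mkdir(exist_ok=True)
    with open(ROOT / "results" / "batch_correction.json", "w") as fh:
        json.dump(out, fh, indent=2)
    (ROOT / "scratch").mkdir(exist_ok=True)
    model.to_json(ROOT / "scratch" / "batch_model.json")

    drop = 1 - out["batch_r2_post"] / out["batch_r2_pre"]
    print(json.dumps(out, indent=2))
    print(f"\nCohort clustering R2 drops {drop:.0%} after adjustment while the "
          "protected disease term is retained -- the intended behaviour of a "
          "protected-design location/scale correction.")


if __name__ == "__main__":
    main()
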