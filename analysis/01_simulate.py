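#!/usr/bin/env python
"""Step 1: simulate the two-wave synthetic cohort.

Writes the raw wave tables and ground truth to scratch/ (large, not tracked)
and a small cohort summary to results/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from devprofiles.cohort import CohortConfig, generate_cohort, plant_missingness, plant_outliers
from devprofiles.ratings import write_wave_table

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"
SEED = 0


def main() -> None:
    SCRATCH.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    cfg = CohortConfig(seed=SEED)
    wave1, wave2, truth = generate_cohort(cfg)
    wave1 = plant_missingness(wave1, cfg.missing_rate, cfg.seed)
    wave2 = plant_missingness(wave2, cfg.missing_rate, cfg.seed + 1)
    wave1, out1 = plant_outliers(wave1, cfg.n_uni_outliers, cfg.n_multi_outliers, cfg.seed)
    wave2, out2 = plant_outliers(wave2, cfg.n_uni_outliers, cfg.n_multi_outliers, cfg.seed + 1)
    truth.outlier_ids_w1, truth.outlier_ids_w2 = out1, out2

    write_wave_table(wave1, SCRATCH / "wave1_raw.csv")
    write_wave_table(wave2, SCRATCH / "wave2_raw.csv")
    truth.to_json(SCRATCH / "ground_truth.json")

    summary = {
        "seed": SEED,
        "n_subjects": cfg.n_subjects,
        "n_items": cfg.n_items,
        "n_factors": cfg.n_factors,
        "missing_rate_wave1": round(float(wave1.missing_mask.mean()), 4),
        "missing_rate_wave2": round(float(wave2.missing_mask.mean()), 4),
        "planted_outliers_per_wave": cfg.n_uni_outliers + cfg.n_multi_outliers,
        "wave1_cluster_sizes": np.bincount(truth.labels_w1).tolist(),
        "wave2_cluster_sizes": np.bincount(truth.labels_w2).tolist(),
    }
    with open(RESULTS / "01_cohort_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print(pd.Series(summary).to_string())


if __name__ == "__main__":
    main()
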