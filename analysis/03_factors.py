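#!/usr/bin/env python
"""Step 3: polychoric EFA with varimax rotation and factor scoring per wave.

Reads the cleaned wave tables from scratch/, writes rotated loadings and a
variance-explained summary to results/, and factor scores to scratch/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from devprofiles.factors import efa, factor_scores
from devprofiles.polychoric import polychoric_matrix
from devprofiles.ratings import ordinal_items, read_wave_table

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"
N_FACTORS = 6


def factor_wave(name: str) -> dict:
    wave = read_wave_table(SCRATCH / f"{name}_clean.csv", ordinal_items(40))
    R = polychoric_matrix(wave.scores)
    model = efa(R, N_FACTORS)
    fs = factor_scores(wave.scores, R, model)
    pd.DataFrame(
        model.loadings,
        index=wave.item_names,
        columns=[f"factor_{j + 1}" for j in range(N_FACTORS)],
    ).round(4).to_csv(RESULTS / f"03_loadings_{name}.csv")
    np.savez(
        SCRATCH / f"{name}_scores.npz", scores=fs.scores, subject_ids=wave.subject_ids
    )
    return {
        "variance_explained": round(model.total_variance, 4),
        "per_factor": [round(v, 4) for v in model.proportion_variance],
        "heywood": model.heywood,
        "max_uniqueness": round(float(model.uniquenesses.max()), 4),
    }


def main() -> None:
    summary = {"wave1": factor_wave("wave1"), "wave2": factor_wave("wave2")}
    with open(RESULTS / "03_factor_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
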