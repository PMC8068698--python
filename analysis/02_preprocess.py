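#!/usr/bin/env python
"""Step 2: screen, impute, remove outliers, and discretise each wave.

Reads the raw wave tables from scratch/, writes the cleaned tables back to
scratch/ and CONSORT-style exclusion counts to results/.
"""

import json
from pathlib import Path

import numpy as np

from devprofiles import preprocess
from devprofiles.ratings import analogue_items, ordinal_items, read_wave_table, write_wave_table

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"
MAX_MISSING = 5
DISCRETISE_LEVELS = 4

# The raw files can hold out-of-range entries (data errors that the outlier
# screen exists to catch), so parse with permissive analogue bounds and then
# restore the instrument's true item metadata for the preprocessing chain.
def clean(name: str, item_meta) -> dict:
    wave = read_wave_table(
        SCRATCH / f"{name}_raw.csv", analogue_items(len(item_meta), low=-1e6, high=1e6)
    )
    wave.item_meta = list(item_meta)
    screened, rep_missing = preprocess.screen_missing(wave, MAX_MISSING)
    completed, _, _, n_iter = preprocess.em_impute(screened)
    keep, rep_out = preprocess.remove_outliers(completed.scores, completed.subject_ids)
    cleaned = completed.subset(np.nonzero(keep)[0])
    if any(m.kind == "analogue" for m in cleaned.item_meta):
        cleaned = preprocess.discretise_wave(cleaned, DISCRETISE_LEVELS)
    write_wave_table(cleaned, SCRATCH / f"{name}_clean.csv")
    return {
        "n_input": wave.n_subjects,
        "n_excluded_missing": len(rep_missing.excluded_missing_ids),
        "em_iterations": n_iter,
        "n_excluded_univariate": len(rep_out.excluded_univariate_ids),
        "n_excluded_multivariate": len(rep_out.excluded_multivariate_ids),
        "mahalanobis_cutoff": round(rep_out.mahalanobis_cutoff, 2),
        "n_final": cleaned.n_subjects,
    }


def main() -> None:
    consort = {
        "wave1": clean("wave1", analogue_items(40)),
        "wave2": clean("wave2", ordinal_items(40)),
    }
    with open(RESULTS / "02_consort.json", "w") as fh:
        json.dump(consort, fh, indent=2)
    print(json.dumps(consort, indent=2))


if __name__ == "__main__":
    main()
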