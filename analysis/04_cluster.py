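#!/usr/bin/env python
"""Step 4: hybrid hierarchical clustering of the factor scores per wave.

Writes Calinski-Harabasz profiles, silhouettes, and cluster profiles with
Cohen's d star labels to results/; cluster labels go to scratch/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from devprofiles import clustering

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"
SEED = 0
K = {"wave1": 7, "wave2": 6}
K_RANGE = range(2, 11)


def cluster_wave(name: str) -> dict:
    data = np.load(SCRATCH / f"{name}_scores.npz")
    X, subject_ids = data["scores"], data["subject_ids"]
    tree = clustering.hybrid_tree(X, seed=SEED)
    prof = clustering.ch_profile(X, tree, K_RANGE)
    pd.DataFrame(
        {
            "k": list(prof["ch"]),
            "calinski_harabasz": [round(v, 3) for v in prof["ch"].values()],
            "pct_change_to_next_k": [
                round(prof["percent_change"][k], 2) if k in prof["percent_change"] else ""
                for k in prof["ch"]
            ],
            "extremum": [prof["extrema"].get(k, "") for k in prof["ch"]],
        }
    ).to_csv(RESULTS / f"04_ch_profile_{name}.csv", index=False)

    part = clustering.cut_tree(tree, K[name])
    sil = clustering.silhouette(squareform(pdist(X)), part.labels)
    rows = []
    for p in clustering.cluster_profiles(X, part):
        for j in range(X.shape[1]):
            rows.append(
                {
                    "cluster": p.cluster,
                    "size": p.size,
                    "share": round(p.share, 4),
                    "factor": j + 1,
                    "mean": round(p.factor_means[j], 3),
                    "cohens_d": round(p.cohens_d[j], 3),
                    "stars": p.stars[j],
                }
            )
    pd.DataFrame(rows).to_csv(RESULTS / f"04_cluster_profiles_{name}.csv", index=False)
    np.savez(SCRATCH / f"{name}_labels.npz", labels=part.labels, subject_ids=subject_ids)
    return {
        "k": K[name],
        "silhouette_mean": round(sil["mean"], 4),
        "ch_at_k": round(prof["ch"][K[name]], 2),
        "cluster_sizes": np.bincount(part.labels)[1:].tolist(),
    }


def main() -> None:
    summary = {"wave1": cluster_wave("wave1"), "wave2": cluster_wave("wave2")}
    with open(RESULTS / "04_cluster_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
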