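#!/usr/bin/env python
"""Step 6: group-by-domain ANOVA, paired domain change, and power analysis.

Mixed ANOVA of cluster group x factor domain per wave (with Mauchly and
Greenhouse-Geisser handling), congruence-matched paired t-tests of domain
change across waves, and the noncentral-F power numbers.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from devprofiles.inference import (
    anova_detectable_f,
    anova_min_n,
    paired_ttest,
    rm_anova,
)

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"


def anova_block(name: str) -> dict:
    X = np.load(SCRATCH / f"{name}_scores.npz")["scores"]
    labels = np.load(SCRATCH / f"{name}_labels.npz")["labels"]
    res = rm_anova(X, labels)
    return {
        "group": {"F": round(res.group.F, 3), "df1": res.group.df1, "df2": res.group.df2,
                  "p": round(res.group.p, 6)},
        "domain": {"F": round(res.domain.F, 3), "p": round(res.domain.p, 6),
                   "p_gg": round(res.domain.p_gg, 6)},
        "interaction": {"F": round(res.interaction.F, 3), "p": round(res.interaction.p, 6),
                        "p_gg": round(res.interaction.p_gg, 6)},
        "mauchly_w": round(res.mauchly_w, 4),
        "mauchly_p": round(res.mauchly_p, 6),
        "gg_epsilon": round(res.epsilon, 4),
    }


def main() -> None:
    out = {"anova_wave1": anova_block("wave1"), "anova_wave2": anova_block("wave2")}

    s1 = np.load(SCRATCH / "wave1_scores.npz")
    s2 = np.load(SCRATCH / "wave2_scores.npz")
    ids1 = {int(s): i for i, s in enumerate(s1["subject_ids"])}
    ids2 = {int(s): i for i, s in enumerate(s2["subject_ids"])}
    shared = sorted(set(ids1) & set(ids2))
    X1 = s1["scores"][[ids1[s] for s in shared]]
    X2 = s2["scores"][[ids2[s] for s in shared]]
    # Match wave-2 factors to wave-1 factors by score correlation, then test
    # per-domain change on the shared subjects.
    corr = np.abs(np.corrcoef(X1.T, X2.T)[: X1.shape[1], X1.shape[1]:])
    paired = {}
    used: set[int] = set()
    for j in range(X1.shape[1]):
        order = [c for c in np.argsort(corr[j])[::-1] if c not in used]
        m = int(order[0])
        used.add(m)
        t, df, p, d = paired_ttest(X1[:, j], X2[:, m])
        paired[f"factor_{j + 1}"] = {
            "wave2_factor": m + 1,
            "score_correlation": round(float(corr[j, m]), 3),
            "t": round(t, 3), "df": df, "p": round(p, 6), "d": round(d, 4),
        }
    out["paired_domain_change"] = paired

    out["power"] = {
        "min_n_f010_6domains": anova_min_n(0.1, 6, 0.05, 0.95),
        "detectable_f_n12134": round(anova_detectable_f(12134, 6, 0.05, 0.95), 4),
        "detectable_f_n6744": round(anova_detectable_f(6744, 6, 0.05, 0.95), 4),
    }
    with open(RESULTS / "06_inference.json", "w") as fh:
        json.dump(out, fh, indent=2)
    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
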