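"""End-to-end pipeline: simulate -> clean -> factor -> cluster -> compare -> transitions.

``run_pipeline`` executes the whole workflow on a configuration and writes a
report bundle (CONSORT-style exclusion counts, loading tables, cluster
diagnostics and profiles, the Fowlkes-Mallows comparison, the transition table
and predictor contrasts) as CSV/JSON under the configured output directory.
All randomness flows from the configured seeds.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, compare, factors, inference, preprocess, transitions
from .cohort import CohortConfig, generate_cohort, plant_missingness, plant_outliers
from .polychoric import polychoric_matrix
from .ratings import RatingMatrix

log = logging.getLogger("devprofiles")


@dataclass
class PipelineConfig:
    """Settings for one end-to-end run."""

    out_dir: str = "results/pipeline"
    # Simulation (used when no input files are given).
    cohort: CohortConfig = field(default_factory=CohortConfig)
    # Preprocessing thresholds.
    max_missing: int = 5
    z_thresh: float = 3.0
    alpha_outlier: float = 0.001
    discretise_levels: int = 4
    # Factor settings.
    n_factors: int = 6
    run_parallel_analysis: bool = False
    n_sim: int = 100
    run_bootstrap: bool = False
    n_boot: int = 100
    # Clustering.
    k_w1: int = 7
    k_w2: int = 6
    k_range: tuple[int, int] = (2, 10)
    n_restarts: int = 10
    # Comparison / transitions.
    k_compare_a: int = 4
    k_compare_b: int = 4
    n_perm: int = 1000
    seed: int = 0

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["cohort"] = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in asdict(self.cohort).items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        cohort = CohortConfig(**d.pop("cohort", {}))
        if "k_range" in d:
            d["k_range"] = tuple(d["k_range"])
        return cls(cohort=cohort, **d)


def _round6(x):
    """Recursively round floats to 6 significant digits for report output."""
    if isinstance(x, float):
        return float(f"{x:.6g}")
    if isinstance(x, dict):
        return {k: _round6(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round6(v) for v in x]
    return x


def _setup_logging(out_dir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s [%(name)s] %(message)s")
    for h in (logging.StreamHandler(sys.stderr), logging.FileHandler(out_dir / "run.log", mode="w")):
        h.setFormatter(fmt)
        log.addHandler(h)


def _clean_wave(wave: RatingMatrix, cfg: PipelineConfig, name: str) -> tuple[RatingMatrix, dict]:
    """Screen missing, EM-impute, remove outliers, discretise analogue items."""
    screened, rep_missing = preprocess.screen_missing(wave, cfg.max_missing)
    log.info("%s: %d subjects excluded for missingness", name, len(rep_missing.excluded_missing_ids))
    completed, _, _, n_iter = preprocess.em_impute(screened)
    log.info("%s: EM imputation converged in %d iterations", name, n_iter)
    keep, rep_out = preprocess.remove_outliers(
        completed.scores, completed.subject_ids, cfg.z_thresh, cfg.alpha_outlier
    )
    cleaned = completed.subset(np.nonzero(keep)[0])
    if any(m.kind == "analogue" for m in cleaned.item_meta):
        cleaned = preprocess.discretise_wave(cleaned, cfg.discretise_levels)
    consort = {
        "n_input": wave.n_subjects,
        "n_excluded_missing": int(len(rep_missing.excluded_missing_ids)),
        "n_excluded_univariate": int(len(rep_out.excluded_univariate_ids)),
        "n_excluded_multivariate": int(len(rep_out.excluded_multivariate_ids)),
        "n_final": cleaned.n_subjects,
        "max_missing": cfg.max_missing,
        "z_thresh": cfg.z_thresh,
        "mahalanobis_cutoff": rep_out.mahalanobis_cutoff,
    }
    return cleaned, consort


def _factor_wave(wave: RatingMatrix, cfg: PipelineConfig, name: str, out: Path) -> tuple:
    R = polychoric_matrix(wave.scores)
    if cfg.run_parallel_analysis:
        k_pa = factors.parallel_analysis(wave.scores, cfg.n_sim, seed=cfg.seed)
        log.info("%s: parallel analysis suggests %d factors", name, k_pa)
    model = factors.efa(R, cfg.n_factors)
    scores = factors.factor_scores(wave.scores, R, model)
    pd.DataFrame(
        model.loadings,
        index=wave.item_names,
        columns=[f"factor_{j + 1}" for j in range(cfg.n_factors)],
    ).round(6).to_csv(out / f"loadings_{name}.csv")
    return R, model, scores


def _cluster_wave(scores: np.ndarray, cfg: PipelineConfig, name: str, out: Path, k: int):
    from scipy.spatial.distance import pdist, squareform

    tree = clustering.hybrid_tree(scores, seed=cfg.seed, n_restarts=cfg.n_restarts)
    ks = range(cfg.k_range[0], cfg.k_range[1] + 1)
    prof = clustering.ch_profile(scores, tree, ks)
    pd.DataFrame(
        {
            "k": list(prof["ch"].keys()),
            "calinski_harabasz": list(prof["ch"].values()),
            "percent_change": [prof["percent_change"].get(k_) for k_ in prof["ch"]],
            "extremum": [prof["extrema"].get(k_, "") for k_ in prof["ch"]],
        }
    ).round(6).to_csv(out / f"ch_profile_{name}.csv", index=False)
    part = clustering.cut_tree(tree, k)
    sil = clustering.silhouette(squareform(pdist(scores)), part.labels)
    pd.DataFrame(
        {"cluster": list(sil["per_cluster"].keys()), "silhouette": list(sil["per_cluster"].values())}
    ).round(6).to_csv(out / f"silhouette_{name}.csv", index=False)
    profiles = clustering.cluster_profiles(scores, part)
    rows = []
    for p in profiles:
        for j in range(scores.shape[1]):
            rows.append(
                {
                    "cluster": p.cluster,
                    "size": p.size,
                    "share": p.share,
                    "factor": j + 1,
                    "mean": p.factor_means[j],
                    "cohens_d": p.cohens_d[j],
                    "stars": p.stars[j],
                }
            )
    pd.DataFrame(rows).round(6).to_csv(out / f"cluster_profiles_{name}.csv", index=False)
    with open(out / f"dendrogram_{name}.json", "w") as fh:
        json.dump(tree.to_merge_list(), fh)
    np.savetxt(out / f"linkage_{name}.txt", tree.to_linkage(), fmt="%.6g")
    return tree, part, sil


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the report bundle as a dict."""
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    t0 = time.time()
    log.info("pipeline start, seed=%d", cfg.seed)

    wave1, wave2, truth = generate_cohort(cfg.cohort)
    wave1 = plant_missingness(wave1, cfg.cohort.missing_rate, cfg.cohort.seed)
    wave2 = plant_missingness(wave2, cfg.cohort.missing_rate, cfg.cohort.seed + 1)
    wave1, out_ids1 = plant_outliers(
        wave1, cfg.cohort.n_uni_outliers, cfg.cohort.n_multi_outliers, cfg.cohort.seed
    )
    wave2, out_ids2 = plant_outliers(
        wave2, cfg.cohort.n_uni_outliers, cfg.cohort.n_multi_outliers, cfg.cohort.seed + 1
    )
    truth.outlier_ids_w1, truth.outlier_ids_w2 = out_ids1, out_ids2

    clean1, consort1 = _clean_wave(wave1, cfg, "wave1")
    clean2, consort2 = _clean_wave(wave2, cfg, "wave2")
    with open(out / "consort.json", "w") as fh:
        json.dump(_round6({"wave1": consort1, "wave2": consort2}), fh, indent=2)

    R1, model1, fs1 = _factor_wave(clean1, cfg, "wave1", out)
    R2, model2, fs2 = _factor_wave(clean2, cfg, "wave2", out)

    tree1, part1, sil1 = _cluster_wave(fs1.scores, cfg, "wave1", out, cfg.k_w1)
    tree2, part2, sil2 = _cluster_wave(fs2.scores, cfg, "wave2", out, cfg.k_w2)

    # Cross-wave comparison on subjects retained in both waves.
    ids1 = {int(s): i for i, s in enumerate(clean1.subject_ids)}
    ids2 = {int(s): i for i, s in enumerate(clean2.subject_ids)}
    shared = sorted(set(ids1) & set(ids2))
    la = np.array([part1.labels[ids1[s]] for s in shared])
    lb = np.array([part2.labels[ids2[s]] for s in shared])
    fm = compare.fm_permutation_test(
        clustering.cut_tree(tree1, cfg.k_compare_a).labels[[ids1[s] for s in shared]],
        cfg.k_compare_a,
        clustering.cut_tree(tree2, cfg.k_compare_b).labels[[ids2[s] for s in shared]],
        cfg.k_compare_b,
        n_perm=cfg.n_perm,
        seed=cfg.seed,
    )
    with open(out / "fm_result.json", "w") as fh:
        json.dump(
            _round6(
                {
                    "b_index": fm.b_index,
                    "k_a": fm.k_a,
                    "k_b": fm.k_b,
                    "null_mean": fm.null_mean,
                    "null_var": fm.null_var,
                    "n_permutations": fm.n_permutations,
                    "p_value": fm.p_value,
                }
            ),
            fh,
            indent=2,
        )

    table = transitions.transition_table(la, lb)
    table = transitions.cellwise_ztests(table)
    table.to_frame().round(6).to_csv(out / "transition_table.csv", index=False)
    row_chi2 = {
        int(r): dict(zip(("chi2", "df", "p"), transitions.equal_split_chi2(table.counts[i])))
        for i, r in enumerate(table.row_labels)
    }

    # Statistics stage: mixed ANOVA of cluster x factor domain per wave,
    # cluster-vs-sample contrasts, and paired domain change on shared subjects.
    stats_report = {}
    for name, fs, part in (("wave1", fs1, part1), ("wave2", fs2, part2)):
        an = inference.rm_anova(fs.scores, part.labels)
        stats_report[f"anova_{name}"] = {
            "group": asdict(an.group),
            "domain": asdict(an.domain),
            "interaction": asdict(an.interaction),
            "mauchly_w": an.mauchly_w,
            "mauchly_p": an.mauchly_p,
            "gg_epsilon": an.epsilon,
        }
        rows = []
        for j in range(fs.scores.shape[1]):
            for c, r in inference.contrast_vs_sample(fs.scores, part.labels, j).items():
                rows.append({"cluster": c, "factor": j + 1, **r})
        pd.DataFrame(rows).round(6).to_csv(out / f"contrasts_{name}.csv", index=False)
    # Match wave-2 factors to wave-1 factors by loading congruence (same items),
    # then test per-domain change across waves on the shared subjects.
    idx1 = [ids1[s] for s in shared]
    idx2 = [ids2[s] for s in shared]
    congr = np.abs(model1.loadings.T @ model2.loadings) / np.outer(
        np.linalg.norm(model1.loadings, axis=0), np.linalg.norm(model2.loadings, axis=0)
    )
    paired = {}
    used = set()
    for j in range(congr.shape[0]):
        order = [c for c in np.argsort(congr[j])[::-1] if c not in used]
        m = int(order[0])
        used.add(m)
        t, dof, p, d = inference.paired_ttest(fs1.scores[idx1, j], fs2.scores[idx2, m])
        paired[f"factor_{j + 1}"] = {
            "wave2_factor": m + 1, "congruence": float(congr[j, m]),
            "t": t, "df": dof, "p": p, "d": d,
        }
    stats_report["paired_domain_change"] = paired
    stats_report["row_equal_split_chi2"] = row_chi2
    with open(out / "stats.json", "w") as fh:
        json.dump(_round6(stats_report), fh, indent=2)

    # Ground-truth-aware recovery summary.
    truth_l1 = np.array([truth.labels_w1[s - 1] for s in clean1.subject_ids])
    truth_l2 = np.array([truth.labels_w2[s - 1] for s in clean2.subject_ids])

    # Planted-vs-detected transition flags: map each detected cluster to the
    # planted cluster it overlaps most, rebuild the transition table in planted
    # label space, and compare significant cells to the planted direction
    # (row probability above/below the equal split).
    mapped1 = _map_to_truth(part1.labels, truth_l1)
    mapped2 = _map_to_truth(part2.labels, truth_l2)
    tmap = transitions.cellwise_ztests(
        transitions.transition_table(
            np.array([mapped1[ids1[s]] for s in shared]),
            np.array([mapped2[ids2[s]] for s in shared]),
        )
    )
    tm = np.asarray(cfg.cohort.transition_matrix, dtype=float)
    equal_split = 1.0 / tm.shape[1]
    flag_rows = []
    n_agree = n_flagged = 0
    for i, r in enumerate(tmap.row_labels):
        for j, c in enumerate(tmap.col_labels):
            planted = "over" if tm[r, c] > equal_split else "under" if tm[r, c] < equal_split else ""
            detected = tmap.flags[i][j]
            if detected in ("over", "under"):
                n_flagged += 1
                n_agree += detected == planted
            flag_rows.append(
                {"from": int(r), "to": int(c), "planted_direction": planted,
                 "planted_prob": tm[r, c], "detected_flag": detected}
            )
    pd.DataFrame(flag_rows).round(6).to_csv(out / "planted_vs_detected.csv", index=False)

    report = {
        "consort": {"wave1": consort1, "wave2": consort2},
        "fm": {"b_index": fm.b_index, "p_value": fm.p_value},
        "silhouette_mean": {"wave1": sil1["mean"], "wave2": sil2["mean"]},
        "variance_explained": {
            "wave1": model1.total_variance,
            "wave2": model2.total_variance,
        },
        "ari": {
            "wave1": adjusted_rand_index(part1.labels, truth_l1),
            "wave2": adjusted_rand_index(part2.labels, truth_l2),
        },
        "transition_flags": {"n_flagged": n_flagged, "n_direction_agree": n_agree},
        "n_shared": len(shared),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(_round6(report), fh, indent=2)
    log.info("pipeline done in %.1f s", time.time() - t0)
    return report


def _map_to_truth(detected: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Relabel each detected cluster as the truth cluster it overlaps most."""
    detected = np.asarray(detected)
    truth = np.asarray(truth)
    mapped = np.empty_like(truth)
    for c in np.unique(detected):
        members = detected == c
        vals, counts = np.unique(truth[members], return_counts=True)
        mapped[members] = vals[np.argmax(counts)]
    return mapped


def adjusted_rand_index(a: np.ndarray, b: np.ndarray) -> float:
    """Adjusted Rand index between two label vectors (pair-counting form)."""
    a = np.asarray(a)
    b = np.asarray(b)
    ra, ia = np.unique(a, return_inverse=True)
    rb, ib = np.unique(b, return_inverse=True)
    M = np.bincount(ia * rb.size + ib, minlength=ra.size * rb.size).reshape(ra.size, rb.size)
    n = a.size

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(M).sum()
    sum_a = comb2(M.sum(axis=1)).sum()
    sum_b = comb2(M.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb2(n)
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))
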