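"""Childhood -> adolescence transition tables and equal-split tests.

Transitions are tested against an *equal split*: with K destination clusters
the null assumes a fraction 1/K transitions to each.  Row-level chi-squared
goodness-of-fit tests and per-cell one-proportion z-tests (Bonferroni over all
table cells) quantify over- and under-represented transitions.  Predictor
contrasts compare a transition group against its complement with pooled-
variance two-sample t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TransitionTable:
    counts: np.ndarray           # K1 x K2 integer counts
    proportions: np.ndarray      # row-normalised
    row_labels: np.ndarray
    col_labels: np.ndarray
    z: np.ndarray | None = None
    p_raw: np.ndarray | None = None
    p_adj: np.ndarray | None = None
    flags: np.ndarray | None = None  # "over" / "under" / ""
    family_size: int | None = None

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        K1, K2 = self.counts.shape
        for i in range(K1):
            for j in range(K2):
                rows.append(
                    {
                        "from": self.row_labels[i],
                        "to": self.col_labels[j],
                        "count": int(self.counts[i, j]),
                        "proportion": self.proportions[i, j],
                        "z": None if self.z is None else self.z[i, j],
                        "p_adj": None if self.p_adj is None else self.p_adj[i, j],
                        "flag": None if self.flags is None else self.flags[i, j],
                    }
                )
        return pd.DataFrame(rows)

    def to_edge_list(self) -> list[dict]:
        df = self.to_frame()
        return df.to_dict(orient="records")


def transition_table(labels_w1: np.ndarray, labels_w2: np.ndarray) -> TransitionTable:
    """Cross-tabulate matched wave-1/wave-2 cluster labels."""
    a = np.asarray(labels_w1)
    b = np.asarray(labels_w2)
    if a.size != b.size or a.size == 0:
        raise ValueError("need matched non-empty label vectors")
    ra, ia = np.unique(a, return_inverse=True)
    rb, ib = np.unique(b, return_inverse=True)
    counts = np.bincount(ia * rb.size + ib, minlength=ra.size * rb.size).reshape(
        ra.size, rb.size
    )
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        props = np.where(row_sums > 0, counts / row_sums, np.nan)
    return TransitionTable(counts=counts, proportions=props, row_labels=ra, col_labels=rb)


def equal_split_chi2(row_counts: np.ndarray) -> tuple[float, int, float]:
    """Pearson goodness-of-fit of one row against the equal-split null."""
    counts = np.asarray(row_counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("row total must be positive")
    K = counts.size
    expected = total / K
    if expected < 5:
        import warnings

        warnings.warn("expected count below 5; chi-squared approximation is poor")
    stat = float(np.sum((counts - expected) ** 2 / expected))
    df = K - 1
    return stat, df, float(stats.chi2.sf(stat, df))


def cellwise_ztests(table: TransitionTable, alpha: float = 0.05) -> TransitionTable:
    """One-proportion z-tests of each cell against p0 = 1/K_w2, Bonferroni over all cells."""
    counts = table.counts
    K1, K2 = counts.shape
    p0 = 1.0 / K2
    family = K1 * K2
    z = np.full((K1, K2), np.nan)
    p_raw = np.full((K1, K2), np.nan)
    flags = np.full((K1, K2), "", dtype=object)
    for i in range(K1):
        n_row = counts[i].sum()
        if n_row == 0:
            flags[i, :] = "missing"
            continue
        phat = counts[i] / n_row
        se = np.sqrt(p0 * (1 - p0) / n_row)
        z[i] = (phat - p0) / se
        p_raw[i] = 2.0 * stats.norm.sf(np.abs(z[i]))
    p_adj = np.minimum(1.0, p_raw * family)
    sig = p_adj < alpha
    flags[sig & (z > 0)] = "over"
    flags[sig & (z < 0)] = "under"
    return TransitionTable(
        counts=counts,
        proportions=table.proportions,
        row_labels=table.row_labels,
        col_labels=table.col_labels,
        z=z,
        p_raw=p_raw,
        p_adj=p_adj,
        flags=flags,
        family_size=family,
    )


@dataclass
class ContrastResult:
    covariate: str
    mean_in: float
    se_in: float
    mean_out: float
    se_out: float
    t: float
    df: int
    p_raw: float
    p_adj: float
    d: float


def predictor_contrast(
    covariates: pd.DataFrame | dict, in_group: np.ndarray, alpha: float = 0.05
) -> list[ContrastResult]:
    """Pooled-variance t-tests of each covariate: transition group vs complement.

    Missing covariate values are dropped per covariate; Bonferroni adjustment
    runs across the covariates tested in this call.  Cohen's d uses the pooled
    standard deviation.
    """
    df_cov = pd.DataFrame(covariates)
    mask = np.asarray(in_group, dtype=bool)
    if mask.sum() == 0 or (~mask).sum() == 0:
        raise ValueError("both groups must be non-empty")
    m = len(df_cov.columns)
    out = []
    for name in df_cov.columns:
        vals = df_cov[name].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        x1 = vals[mask & ok]
        x2 = vals[~mask & ok]
        n1, n2 = x1.size, x2.size
        sp2 = ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / (n1 + n2 - 2)
        if sp2 <= 0:
            raise ValueError(f"zero pooled variance for covariate {name!r}")
        t = (x1.mean() - x2.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        dof = n1 + n2 - 2
        p = 2.0 * stats.t.sf(abs(t), dof)
        out.append(
            ContrastResult(
                covariate=str(name),
                mean_in=float(x1.mean()),
                se_in=float(x1.std(ddof=1) / np.sqrt(n1)),
                mean_out=float(x2.mean()),
                se_out=float(x2.std(ddof=1) / np.sqrt(n2)),
                t=float(t),
                df=int(dof),
                p_raw=float(p),
                p_adj=float(min(1.0, p * m)),
                d=float((x1.mean() - x2.mean()) / np.sqrt(sp2)),
            )
        )
    return out
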