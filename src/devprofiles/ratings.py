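"""Subject x item rating matrices and their delimited-text round trip.

A :class:`RatingMatrix` holds questionnaire scores for one assessment wave.
Items are either *analogue* (continuous visual-analogue positions in mm on a
declared range, as in the childhood sweep) or *ordinal* (integer levels
``1..levels``, as in the adolescence sweep).  Missing cells are NaN in
``scores`` and True in ``missing_mask``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

MISSING_TOKENS = ("", "NA")


@dataclass(frozen=True)
class ItemScale:
    """Scale descriptor for one questionnaire item."""

    kind: str  # "analogue" | "ordinal"
    low: float = 0.0
    high: float = 100.0
    levels: int = 4

    def __post_init__(self):
        if self.kind not in ("analogue", "ordinal"):
            raise ValueError(f"unknown item scale kind {self.kind!r}")
        if self.kind == "analogue" and not self.high > self.low:
            raise ValueError("analogue scale needs high > low")
        if self.kind == "ordinal" and self.levels < 2:
            raise ValueError("ordinal scale needs >= 2 levels")


def analogue_items(n: int, low: float = 0.0, high: float = 100.0) -> list[ItemScale]:
    return [ItemScale("analogue", low=low, high=high) for _ in range(n)]


def ordinal_items(n: int, levels: int = 4) -> list[ItemScale]:
    return [ItemScale("ordinal", levels=levels) for _ in range(n)]


@dataclass
class RatingMatrix:
    """Scores for one wave, with per-item scale metadata and missingness mask."""

    scores: np.ndarray  # (n_subjects, n_items), NaN where missing
    item_meta: list[ItemScale]
    subject_ids: np.ndarray
    covariates: pd.DataFrame | None = None

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.scores.ndim != 2:
            raise ValueError("scores must be 2-D")
        if self.scores.shape[1] != len(self.item_meta):
            raise ValueError("item_meta length does not match score columns")
        if self.scores.shape[0] != len(self.subject_ids):
            raise ValueError("subject_ids length does not match score rows")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.scores)

    @property
    def n_subjects(self) -> int:
        return self.scores.shape[0]

    @property
    def n_items(self) -> int:
        return self.scores.shape[1]

    @property
    def item_names(self) -> list[str]:
        return [f"item_{i + 1:03d}" for i in range(self.n_items)]

    def copy(self) -> "RatingMatrix":
        return RatingMatrix(
            self.scores.copy(),
            list(self.item_meta),
            self.subject_ids.copy(),
            None if self.covariates is None else self.covariates.copy(),
        )

    def subset(self, row_index: np.ndarray) -> "RatingMatrix":
        cov = None if self.covariates is None else self.covariates.iloc[row_index].reset_index(drop=True)
        return RatingMatrix(self.scores[row_index], list(self.item_meta), self.subject_ids[row_index], cov)

    def validate_ranges(self) -> list[tuple[int, int]]:
        """Return (row, col) coordinates of observed cells outside the declared scale."""
        bad = []
        for j, meta in enumerate(self.item_meta):
            col = self.scores[:, j]
            obs = ~np.isnan(col)
            if meta.kind == "ordinal":
                ok = obs & (col == np.round(col)) & (col >= 1) & (col <= meta.levels)
            else:
                ok = obs & (col >= meta.low) & (col <= meta.high)
            for i in np.nonzero(obs & ~ok)[0]:
                bad.append((int(i), j))
        return bad


def write_wave_table(matrix: RatingMatrix, path) -> None:
    """Write a wave as CSV: subject_id, item_001..item_p, then covariates."""
    df = pd.DataFrame(matrix.scores, columns=matrix.item_names)
    df.insert(0, "subject_id", matrix.subject_ids)
    if matrix.covariates is not None:
        for c in matrix.covariates.columns:
            df[c] = matrix.covariates[c].to_numpy()
    df.to_csv(path, index=False, na_rep="")


def read_wave_table(path, item_meta: Sequence[ItemScale],
                    missing_tokens: Sequence[str] = MISSING_TOKENS) -> RatingMatrix:
    """Parse a delimited wave table, masking missing tokens and validating ranges."""
    df = pd.read_csv(path, na_values=list(missing_tokens), keep_default_na=False)
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: missing subject_id column")
    item_cols = [c for c in df.columns if c.startswith("item_")]
    if len(item_cols) != len(item_meta):
        raise ValueError(
            f"{path}: {len(item_cols)} item columns but {len(item_meta)} item descriptors"
        )
    try:
        scores = df[item_cols].to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: malformed numeric cell ({exc})") from exc
    cov_cols = [c for c in df.columns if c != "subject_id" and not c.startswith("item_")]
    cov = df[cov_cols].reset_index(drop=True) if cov_cols else None
    matrix = RatingMatrix(scores, list(item_meta), df["subject_id"].to_numpy(), cov)
    bad = matrix.validate_ranges()
    if bad:
        cells = ", ".join(f"(row {i + 2}, {item_cols[j]})" for i, j in bad[:10])
        raise ValueError(f"{path}: {len(bad)} cells out of declared range: {cells}")
    return matrix
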