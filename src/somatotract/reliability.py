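"""Inter-rater reliability statistics for expert tract-quality scores.

Expert review of tractography is summarized on a 1 (poor) to 5 (excellent)
scale.  Agreement is quantified by the intraclass correlation coefficient
ICC(2,1) — two-way random effects, absolute agreement, single measure —
from the standard two-way ANOVA mean-squares decomposition, and internal
consistency by Cronbach's alpha (raters treated as items) with Feldt's
F-based confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist


class DegenerateScoresError(ValueError):
    """Raised when the score matrix carries no variance to decompose."""


@dataclass
class ScoreMatrix:
    """Raters x items table of ordinal scores.

    At least 2 raters and 2 items; no missing cells; scores within the
    declared range.
    """

    scores: np.ndarray
    score_range: tuple[float, float] = (1.0, 5.0)
    raters: list[str] | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("scores must be a 2D raters x items array")
        if np.any(~np.isfinite(self.scores)):
            raise ValueError("scores must have no missing cells")
        if self.n_raters < 2 or self.n_items < 2:
            raise ValueError("need at least 2 raters and 2 items")
        lo, hi = self.score_range
        if np.any(self.scores < lo) or np.any(self.scores > hi):
            raise ValueError(f"scores outside the declared range [{lo}, {hi}]")

    @property
    def n_raters(self) -> int:
        return self.scores.shape[0]

    @property
    def n_items(self) -> int:
        return self.scores.shape[1]

    @classmethod
    def from_csv(cls, path, score_range=(1.0, 5.0)) -> "ScoreMatrix":
        """Read a raters x items CSV (first column = rater name)."""
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), score_range, list(df.index))


def _mean_squares(scores: np.ndarray) -> tuple[float, float, float, int, int]:
    """Two-way ANOVA mean squares of an items x raters layout.

    Returns (MSR rows/items, MSC columns/raters, MSE, n_items, k_raters).
    """
    y = scores.T  # items as rows, raters as columns
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_tot = ((y - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc(matrix: ScoreMatrix, form: str = "ICC(2,1)") -> float:
    """Intraclass correlation coefficient of rater agreement.

    Only the two-way random, absolute-agreement, single-measure form
    ICC(2,1) is implemented; the form label is part of the signature so the
    choice is always explicit in reports.
    """
    if form != "ICC(2,1)":
        raise NotImplementedError(f"unsupported ICC form {form!r}")
    msr, msc, mse, n, k = _mean_squares(matrix.scores)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if abs(denom) < 1e-30 or np.allclose(matrix.scores, matrix.scores.flat[0]):
        raise DegenerateScoresError("ICC undefined: no variance in scores")
    return float((msr - mse) / denom)


def cronbach_alpha(
    matrix: ScoreMatrix, ci: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Cronbach's alpha with Feldt's F-method confidence interval.

    Raters are treated as the parallel items: with k raters and item (rater)
    sample variances s_i^2 and total-score variance s_t^2,
    alpha = k/(k-1) * (1 - sum s_i^2 / s_t^2).
    """
    y = matrix.scores  # raters x items
    k = matrix.n_raters
    n = matrix.n_items
    item_vars = y.var(axis=1, ddof=1)  # per-rater variance over items
    total_var = y.sum(axis=0).var(ddof=1)
    if total_var < 1e-30:
        raise DegenerateScoresError("alpha undefined: no variance in totals")
    alpha = k / (k - 1) * (1.0 - item_vars.sum() / total_var)
    df1 = n - 1
    df2 = df1 * (k - 1)
    tail = (1.0 - ci) / 2.0
    lower = 1.0 - (1.0 - alpha) * f_dist.isf(tail, df1, df2)
    upper = 1.0 - (1.0 - alpha) * f_dist.isf(1.0 - tail, df1, df2)
    return float(alpha), (float(lower), float(upper))
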