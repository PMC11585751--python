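"""Reader-agreement statistics for multi-reader PI score tables.

A score table holds the PI percentages assigned by each reader (human
pathologists, the automated scorer, and AI-assisted pathologists) to each
ROI.  Discordance between two readers is summarised by the root mean
squared error (RMSE) of their paired scores; study-level discordance is the
mean of the pairwise RMSEs.  Bland-Altman analysis characterises pairwise
agreement by the mean paired difference and the limits of agreement
mean +/- 1.96 x SD of the differences, the interval expected to contain
about 95 % of differences.  (Some reports label this interval a "95 %
confidence interval"; the formula implemented is the limits-of-agreement
one.)
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ScoreTable",
    "RMSEMatrix",
    "BlandAltmanResult",
    "ErrorHistogram",
    "rmse",
    "rmse_matrix",
    "mean_pairwise_discordance",
    "discordance_reduction",
    "bland_altman",
    "agreement_rate",
    "error_histogram",
]


@dataclass(frozen=True)
class ScoreTable:
    """Readers x ROIs matrix of PI percentages.

    ``scores`` is indexed [reader, roi]; all entries must be finite and in
    [0, 100] — missing data is rejected at construction/load.
    """

    reader_ids: list[str]
    roi_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.shape != (len(self.reader_ids), len(self.roi_ids)):
            raise ValueError("scores shape must be (n_readers, n_rois)")
        if not np.isfinite(s).all():
            raise ValueError("score table contains missing or non-finite cells")
        if s.min() < 0 or s.max() > 100:
            raise ValueError("PI scores must lie in [0, 100]")
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "reader_ids", list(self.reader_ids))
        object.__setattr__(self, "roi_ids", list(self.roi_ids))

    def reader(self, reader_id: str) -> np.ndarray:
        return self.scores[self.reader_ids.index(reader_id)]

    def to_frame(self) -> pd.DataFrame:
        """Rows = ROIs, columns = readers (the CSV layout)."""
        return pd.DataFrame(self.scores.T, index=self.roi_ids, columns=self.reader_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ScoreTable":
        return cls(
            reader_ids=[str(c) for c in df.columns],
            roi_ids=[str(i) for i in df.index],
            scores=df.to_numpy(dtype=float).T,
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "ScoreTable":
        """Load a score CSV: header row of reader ids, one row per ROI,
        first column = ROI id."""
        return cls.from_frame(pd.read_csv(path, index_col=0))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="roi_id")


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root mean squared error between two equal-length score vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("inputs must be equal-length vectors of length >= 1")
    return float(np.sqrt(np.mean((a - b) ** 2)))


@dataclass(frozen=True)
class RMSEMatrix:
    """Symmetric pairwise-RMSE matrix over readers, zero diagonal."""

    reader_ids: list[str]
    values: np.ndarray

    def entry(self, a: str, b: str) -> float:
        return float(
            self.values[self.reader_ids.index(a), self.reader_ids.index(b)]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.reader_ids, columns=self.reader_ids)

    def to_csv(self, path: str | Path) -> None:
        # 2-decimal display precision; full precision stays in memory
        self.to_frame().round(2).to_csv(path, index_label="reader")


def rmse_matrix(table: ScoreTable) -> RMSEMatrix:
    """Pairwise RMSE over all reader pairs of a score table."""
    n = len(table.reader_ids)
    if n < 2:
        raise ValueError("need at least two readers")
    m = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        m[i, j] = m[j, i] = rmse(table.scores[i], table.scores[j])
    return RMSEMatrix(reader_ids=list(table.reader_ids), values=m)


def mean_pairwise_discordance(
    m: RMSEMatrix, readers: list[str] | None = None
) -> float:
    """Mean of the upper-triangle RMSE entries among a subset of readers."""
    ids = list(m.reader_ids) if readers is None else list(readers)
    if len(ids) < 2:
        raise ValueError("need at least two readers")
    idx = [m.reader_ids.index(r) for r in ids]
    vals = [m.values[i, j] for i, j in combinations(idx, 2)]
    return float(np.mean(vals))


def discordance_reduction(pre: float, post: float) -> float:
    """Percent reduction of mean discordance: 100 * (pre - post) / pre."""
    if pre <= 0:
        raise ValueError("pre-assistance discordance must be positive")
    return 100.0 * (pre - post) / pre


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bland-Altman agreement summary for paired scores a vs b (diffs a-b)."""

    mean_diff: float
    sd_diff: float
    n: int
    means: np.ndarray  # per-pair (a+b)/2, the plot x-axis
    diffs: np.ndarray  # per-pair a-b, the plot y-axis

    @property
    def loa_low(self) -> float:
        return self.mean_diff - 1.96 * self.sd_diff

    @property
    def loa_high(self) -> float:
        return self.mean_diff + 1.96 * self.sd_diff


def bland_altman(a: np.ndarray, b: np.ndarray, ddof: int = 1) -> BlandAltmanResult:
    """Mean difference and limits of agreement (mean +/- 1.96 SD of diffs).

    ``ddof=1`` (sample SD) by default; set ``ddof=0`` for the population SD.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length vectors")
    if a.size < 2:
        raise ValueError("Bland-Altman needs at least two pairs (SD undefined)")
    diffs = a - b
    return BlandAltmanResult(
        mean_diff=float(diffs.mean()),
        sd_diff=float(diffs.std(ddof=ddof)),
        n=int(a.size),
        means=(a + b) / 2.0,
        diffs=diffs,
    )


def agreement_rate(n_accepted: int, n_total: int) -> float:
    """Percentage of ROIs whose automated score a reader accepted."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_accepted <= n_total:
        raise ValueError("n_accepted must lie in [0, n_total]")
    return 100.0 * n_accepted / n_total


@dataclass(frozen=True)
class ErrorHistogram:
    """Absolute score differences binned in 10-point brackets.

    Brackets are half-open [0,10), [10,20), ..., with the last bracket
    [90,100] closed.  Counts sum to the number of ROIs.
    """

    edges: np.ndarray  # 0, 10, ..., 100
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        labels = [
            f"[{int(lo)},{int(hi)}" + (")" if hi < self.edges[-1] else "]")
            for lo, hi in zip(self.edges[:-1], self.edges[1:])
        ]
        return pd.DataFrame({"bracket": labels, "count": self.counts})


def error_histogram(manual: np.ndarray, assisted: np.ndarray) -> ErrorHistogram:
    """Bin |manual - assisted| into 10-percentage-point error brackets."""
    manual = np.asarray(manual, dtype=float)
    assisted = np.asarray(assisted, dtype=float)
    if manual.shape != assisted.shape:
        raise ValueError("vectors must have equal length")
    errors = np.abs(manual - assisted)
    edges = np.arange(0, 101, 10)
    counts, _ = np.histogram(errors, bins=edges)  # last bin closed, as required
    return ErrorHistogram(edges=edges, counts=counts)
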