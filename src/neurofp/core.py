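"""Core containers shared across the fingerprinting pipeline.

The unit of raw data is one resting-state run of one subject: a ``T x P``
matrix of region-of-interest (ROI) time courses sampled every ``tr_s``
seconds.  A fingerprint is the strict upper triangle of the ``P x P``
Pearson correlation matrix of those channels (length ``P*(P-1)/2``,
741 edges for the 39-ROI parcellation used throughout).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "RoiTimeSeries",
    "SegmentSpec",
    "FCVector",
    "IdentificationReport",
]


@dataclass
class RoiTimeSeries:
    """One run of ROI time courses.

    Parameters
    ----------
    data : ndarray, shape (T, P)
        Samples by channels.  Must be finite, ``T >= 2``, ``P >= 2``.
    tr_s : float
        Sampling interval (repetition time) in seconds.
    subject_id, run_id : str
        Identity labels; ``(subject_id, run_id)`` is unique within a cohort.
    """

    data: np.ndarray
    tr_s: float
    subject_id: str
    run_id: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"time series must be 2-D, got shape {self.data.shape}")
        t, p = self.data.shape
        if t < 2 or p < 2:
            raise ValueError(f"need at least 2 samples and 2 channels, got {t}x{p}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(
                f"non-finite values in run {self.subject_id}/{self.run_id}"
            )
        if self.tr_s <= 0:
            raise ValueError(f"tr_s must be positive, got {self.tr_s}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples * self.tr_s

    def with_data(self, data: np.ndarray) -> "RoiTimeSeries":
        """Copy carrying the same labels but new samples."""
        return RoiTimeSeries(
            data=data, tr_s=self.tr_s, subject_id=self.subject_id, run_id=self.run_id
        )


@dataclass(frozen=True)
class SegmentSpec:
    """A contiguous temporal window: ``n_samples = floor(length_s / tr_s)``
    samples starting at sample index ``start_index``."""

    length_s: float
    start_index: int
    n_samples: int

    def __post_init__(self) -> None:
        if self.length_s <= 0:
            raise ValueError("segment length must be positive")
        if self.start_index < 0:
            raise ValueError("start_index must be non-negative")
        if self.n_samples < 2:
            raise ValueError(
                f"segment of {self.length_s} s yields {self.n_samples} samples; "
                "at least 2 required"
            )


@dataclass
class FCVector:
    """Vectorized functional-connectivity fingerprint.

    ``values`` is the strict upper triangle of a ``P x P`` correlation matrix
    in row-major order, so its length is ``P*(P-1)/2``.
    """

    values: np.ndarray
    subject_id: str
    run_id: str
    segment: Optional[SegmentSpec] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FC vector contains non-finite entries")
        if np.any(np.abs(self.values) > 1.0 + 1e-12):
            raise ValueError("correlation entries must lie in [-1, 1]")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class IdentificationReport:
    """Outcome of an identification experiment.

    ``records`` has one row per query/anchor with columns
    ``query_subject_id, query_run_id, predicted_subject_id, score``
    (score 1 for a correct identification, 0 otherwise).  ``precision``,
    ``recall`` and ``f1`` are macro-averaged over subjects when predicted
    labels are available.  ``replicates`` optionally carries per-replicate
    accuracies when the experiment was repeated.
    """

    records: pd.DataFrame
    precision: Optional[float] = None
    recall: Optional[float] = None
    f1: Optional[float] = None
    replicates: Optional[np.ndarray] = None
    extra: dict = field(default_factory=dict)

    REQUIRED_COLUMNS = (
        "query_subject_id",
        "query_run_id",
        "predicted_subject_id",
        "score",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"report records missing columns {missing}")
        scores = self.records["score"].to_numpy()
        if not np.isin(scores, [0, 1]).all():
            raise ValueError("scores must be 0 or 1")

    @property
    def accuracy(self) -> float:
        """Mean of the per-query 0/1 scores."""
        return float(self.records["score"].mean())

    @property
    def n_queries(self) -> int:
        return len(self.records)

    def replicate_stats(self) -> tuple[float, float]:
        """Mean and standard deviation over replicate accuracies."""
        if self.replicates is None:
            raise ValueError("report carries no replicate values")
        reps = np.asarray(self.replicates, dtype=float)
        return float(reps.mean()), float(reps.std(ddof=1)) if reps.size > 1 else 0.0
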