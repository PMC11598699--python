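"""Functional-connectivity fingerprints from ROI time series.

The pipeline is: bandpass-filter the full run once (0.01-0.1 Hz, the
standard resting-state band), optionally crop a random contiguous temporal
segment (the data-augmentation primitive), compute the Pearson correlation
matrix across channels, and vectorize its strict upper triangle.

Filtering is applied to full runs before cropping so that short segments do
not inherit filter edge artifacts.  Pearson correlation is invariant to
per-channel affine maps, so z-scoring never changes the resulting
fingerprint; ``zscore`` exists for numerical hygiene and for exporting
normalized arrays.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from scipy import signal

from .core import FCVector, RoiTimeSeries, SegmentSpec

__all__ = [
    "bandpass",
    "zscore",
    "crop_segment",
    "pearson_fc",
    "vectorize_fc",
    "devectorize_fc",
    "fingerprint",
    "n_edges",
    "edge_names",
]

DEFAULT_BAND_HZ = (0.01, 0.1)
_BUTTER_ORDER = 4


def n_edges(n_rois: int) -> int:
    """Number of unique off-diagonal edges: P*(P-1)/2."""
    return n_rois * (n_rois - 1) // 2


def edge_names(n_rois: int) -> list[str]:
    """Column names ``e_{i}_{j}`` for the vectorized upper triangle."""
    ii, jj = np.triu_indices(n_rois, k=1)
    return [f"e_{i}_{j}" for i, j in zip(ii, jj)]


def bandpass(
    ts: RoiTimeSeries,
    low_hz: float = DEFAULT_BAND_HZ[0],
    high_hz: float = DEFAULT_BAND_HZ[1],
) -> RoiTimeSeries:
    """Zero-phase Butterworth bandpass of every channel.

    A 4th-order Butterworth filter is applied forward and backward
    (``filtfilt``), preserving shape and phase.

    Raises
    ------
    ValueError
        If the band is not strictly inside (0, Nyquist) where
        Nyquist = 1 / (2 * tr_s).
    """
    fs = 1.0 / ts.tr_s
    nyquist = fs / 2.0
    if not (0.0 < low_hz < high_hz):
        raise ValueError(f"need 0 < low_hz < high_hz, got ({low_hz}, {high_hz})")
    if high_hz >= nyquist:
        raise ValueError(
            f"high cutoff {high_hz} Hz is at or above the Nyquist frequency "
            f"{nyquist:.4g} Hz for tr_s={ts.tr_s}"
        )
    sos = signal.butter(
        _BUTTER_ORDER, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos"
    )
    filtered = signal.sosfiltfilt(sos, ts.data, axis=0)
    return ts.with_data(np.ascontiguousarray(filtered))


def zscore(ts: RoiTimeSeries) -> RoiTimeSeries:
    """Standardize every channel to mean 0 and unit variance.

    Raises
    ------
    ValueError
        Naming the first zero-variance channel, if any.
    """
    mean = ts.data.mean(axis=0)
    std = ts.data.std(axis=0)
    zero = np.flatnonzero(std == 0.0)
    if zero.size:
        raise ValueError(
            f"channel {int(zero[0])} of run {ts.subject_id}/{ts.run_id} "
            "has zero variance; cannot z-score"
        )
    return ts.with_data((ts.data - mean) / std)


def crop_segment(
    ts: RoiTimeSeries, length_s: float, rng: np.random.Generator
) -> tuple[RoiTimeSeries, SegmentSpec]:
    """Extract a random contiguous temporal segment of ``length_s`` seconds.

    The start index is drawn uniformly from ``{0, ..., T - n_samples}`` with
    ``n_samples = floor(length_s / tr_s)``.  No padding: requesting a
    segment longer than the run is an error.
    """
    n = math.floor(length_s / ts.tr_s)
    t = ts.n_samples
    if n > t:
        raise ValueError(
            f"segment of {length_s} s ({n} samples) exceeds run length "
            f"{t} samples ({ts.duration_s:.1f} s)"
        )
    if n < 2:
        raise ValueError(f"segment of {length_s} s yields {n} < 2 samples")
    start = int(rng.integers(0, t - n + 1))
    spec = SegmentSpec(length_s=length_s, start_index=start, n_samples=n)
    return ts.with_data(ts.data[start : start + n]), spec


def pearson_fc(ts: RoiTimeSeries) -> np.ndarray:
    """Pearson correlation matrix across channels (P x P).

    Symmetric with unit diagonal; entries clipped to [-1, 1] to absorb
    floating-point overshoot.  Constant channels make the correlation
    undefined and raise.
    """
    std = ts.data.std(axis=0)
    zero = np.flatnonzero(std == 0.0)
    if zero.size:
        raise ValueError(
            f"channel {int(zero[0])} is constant over the window "
            f"[{ts.n_samples} samples] of run {ts.subject_id}/{ts.run_id}; "
            "Pearson correlation undefined"
        )
    fc = np.corrcoef(ts.data, rowvar=False)
    fc = np.clip((fc + fc.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(fc, 1.0)
    return fc


def vectorize_fc(fc: np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Strict upper triangle of a symmetric matrix, row-major order.

    For P ROIs the result has length P*(P-1)/2 (741 for P=39).
    """
    fc = np.asarray(fc, dtype=float)
    if fc.ndim != 2 or fc.shape[0] != fc.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {fc.shape}")
    if not np.allclose(fc, fc.T, atol=atol):
        raise ValueError("matrix is not symmetric within tolerance")
    ii, jj = np.triu_indices(fc.shape[0], k=1)
    return fc[ii, jj].copy()


def devectorize_fc(values: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vectorize_fc`: rebuild the symmetric matrix with a
    unit diagonal."""
    values = np.asarray(values, dtype=float).ravel()
    # solve m*(m-1)/2 = len
    p = int(round((1 + math.sqrt(1 + 8 * values.size)) / 2))
    if p * (p - 1) // 2 != values.size:
        raise ValueError(f"vector of length {values.size} is not a strict upper triangle")
    fc = np.eye(p)
    ii, jj = np.triu_indices(p, k=1)
    fc[ii, jj] = values
    fc[jj, ii] = values
    return fc


def fingerprint(ts: RoiTimeSeries, segment: Optional[SegmentSpec] = None) -> FCVector:
    """Compute the FC fingerprint of a (possibly cropped) run."""
    return FCVector(
        values=vectorize_fc(pearson_fc(ts)),
        subject_id=ts.subject_id,
        run_id=ts.run_id,
        segment=segment,
    )
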