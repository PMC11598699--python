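"""Seeded multi-subject, multi-run ROI time-series cohorts.

The generator plants subject identity in the covariance structure — the
property fingerprinting methods rely on.  Every subject's correlation
matrix is built from a low-rank factor model

    C_s = B0 B0' + delta^2 Bs Bs' + eps0 I

with a shared loading matrix ``B0`` (common resting-state structure), a
subject-specific loading ``Bs`` scaled by ``delta`` (identity), and a
diagonal ridge ``eps0`` guaranteeing positive-definiteness.  Each run adds
a run-specific factor term scaled by ``rho`` (session noise) before
renormalization to a correlation matrix, so within-subject similarity
exceeds between-subject similarity whenever ``delta`` dominates ``rho``.
Samples are Gaussian with that run-level correlation, smoothed channelwise
by a variance-preserving AR(1) recursion to give the series low-frequency
content; the smoothing leaves the cross-channel correlation intact.

Defaults mirror a cohort of ~15-minute resting-state runs with 39 ROIs
and 4 runs per subject.  The sampling interval is configurable (1.4 s by
default); all segment lengths elsewhere in the package are specified in
seconds and converted by ``floor(seconds / tr_s)``.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .core import RoiTimeSeries

__all__ = [
    "SyntheticConfig",
    "GroundTruthCohort",
    "make_subject_covariances",
    "simulate_run",
    "make_cohort",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-generation parameters.

    Parameters
    ----------
    n_subjects, n_runs, n_rois : int
        Cohort shape; at least two runs per subject so that every subject
        has a positive instance for identification.
    duration_s, tr_s : float
        Run length and sampling interval in seconds;
        ``T = floor(duration_s / tr_s)`` samples per run.
    k_base, k_subject : int
        Ranks of the shared and subject-specific loading matrices.
    delta : float
        Subject-separation scale; 0 makes all subjects identical.
    rho : float
        Run-perturbation scale; 0 makes runs exact replicas in law.
    eps0 : float
        Diagonal jitter, strictly positive (positive-definite guarantee).
    ar_phi : float
        AR(1) smoothing coefficient in [0, 1).
    seed : int
        Master seed; the cohort is a pure function of the config.
    """

    n_subjects: int
    n_runs: int = 4
    n_rois: int = 39
    duration_s: float = 900.0
    tr_s: float = 1.4
    k_base: int = 10
    k_subject: int = 5
    delta: float = 1.0
    rho: float = 0.3
    eps0: float = 1.0
    ar_phi: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2 (identification needs a positive)")
        if self.n_rois < 2:
            raise ValueError("n_rois must be >= 2")
        if self.duration_s <= 0 or self.tr_s <= 0:
            raise ValueError("duration_s and tr_s must be positive")
        if self.n_samples < 2:
            raise ValueError(
                f"floor({self.duration_s}/{self.tr_s}) = {self.n_samples} < 2 samples"
            )
        if self.k_base < 1 or self.k_subject < 1:
            raise ValueError("factor counts must be positive")
        if self.delta < 0 or self.rho < 0:
            raise ValueError("delta and rho must be non-negative")
        if self.eps0 <= 0:
            raise ValueError("eps0 must be strictly positive")
        if not (0.0 <= self.ar_phi < 1.0):
            raise ValueError("ar_phi must lie in [0, 1)")

    @property
    def n_samples(self) -> int:
        return math.floor(self.duration_s / self.tr_s)


@dataclass
class GroundTruthCohort:
    """Generated cohort plus the latent correlation targets.

    ``subject_corrs`` maps subject_id to the subject-level correlation
    matrix; ``run_corrs`` maps (subject_id, run_id) to the run-level
    sampling target.  Both are retained for property checks.
    """

    config: SyntheticConfig
    subject_corrs: dict[str, np.ndarray]
    run_corrs: dict[tuple[str, str], np.ndarray]
    runs: list[RoiTimeSeries] = field(default_factory=list)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.subject_corrs.keys())

    @property
    def run_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for ts in self.runs:
            seen.setdefault(ts.run_id, None)
        return list(seen.keys())


def _cov_to_corr(cov: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return corr


def _check_correlation(mat: np.ndarray, what: str) -> None:
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise AssertionError(f"{what} not symmetric")
    if not np.allclose(np.diag(mat), 1.0, atol=1e-10):
        raise AssertionError(f"{what} diagonal not unit")
    eigmin = np.linalg.eigvalsh(mat)[0]
    if eigmin <= 0:
        raise AssertionError(f"{what} not positive definite (min eig {eigmin:.3g})")


def subject_label(i: int) -> str:
    return f"sub-{i:03d}"


def run_label(j: int) -> str:
    return f"run-{j + 1}"


def _run_rng(cfg: SyntheticConfig, subject_id: str, run_id: str) -> np.random.Generator:
    # stable per-(seed, subject, run) stream independent of call order
    key = zlib.crc32(f"{subject_id}/{run_id}".encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, key]))


def make_subject_covariances(cfg: SyntheticConfig) -> list[np.ndarray]:
    """Per-subject correlation matrices from the shared + subject factor model.

    Deterministic given ``cfg.seed``: the shared loading ``B0`` is drawn
    once, then one subject loading per subject, in subject order.
    """
    ss = np.random.SeedSequence([cfg.seed, 0xB0])
    rng = np.random.default_rng(ss)
    b0 = rng.standard_normal((cfg.n_rois, cfg.k_base))
    shared = b0 @ b0.T
    corrs = []
    for _ in range(cfg.n_subjects):
        bs = rng.standard_normal((cfg.n_rois, cfg.k_subject))
        cov = shared + cfg.delta**2 * (bs @ bs.T) + cfg.eps0 * np.eye(cfg.n_rois)
        corr = _cov_to_corr(cov)
        _check_correlation(corr, "subject correlation")
        corrs.append(corr)
    return corrs


def _ar1_smooth(x: np.ndarray, phi: float) -> np.ndarray:
    """Variance-preserving channelwise AR(1): y_t = phi*y_{t-1} + sqrt(1-phi^2)*x_t,
    y_0 = x_0.  Identical weights across channels, so per-timepoint
    cross-channel correlation is unchanged."""
    if phi == 0.0:
        return x
    y = np.empty_like(x)
    y[0] = x[0]
    c = math.sqrt(1.0 - phi * phi)
    for t in range(1, x.shape[0]):
        y[t] = phi * y[t - 1] + c * x[t]
    return y


def simulate_run(
    sigma_s: np.ndarray,
    cfg: SyntheticConfig,
    subject_id: str,
    run_id: str,
) -> tuple[RoiTimeSeries, np.ndarray]:
    """Sample one run targeting a run-perturbed version of ``sigma_s``.

    The run-level target adds a run-specific factor term
    ``rho^2 * Cr Cr'`` (``Cr``: P x k_subject standard normal) to the
    subject matrix and renormalizes to a correlation matrix.  Returns the
    time series and the run-level correlation target.
    """
    sigma_s = np.asarray(sigma_s, dtype=float)
    if sigma_s.shape != (cfg.n_rois, cfg.n_rois):
        raise ValueError(
            f"subject matrix shape {sigma_s.shape} != ({cfg.n_rois}, {cfg.n_rois})"
        )
    t = cfg.n_samples
    if t < 2:
        raise ValueError("configuration yields fewer than 2 samples per run")
    rng = _run_rng(cfg, subject_id, run_id)
    if cfg.rho > 0:
        cr = rng.standard_normal((cfg.n_rois, cfg.k_subject))
        target = _cov_to_corr(sigma_s + cfg.rho**2 * (cr @ cr.T))
    else:
        # keep the stream layout identical so rho only rescales the term
        rng.standard_normal((cfg.n_rois, cfg.k_subject))
        target = sigma_s.copy()
    _check_correlation(target, f"run target {subject_id}/{run_id}")
    chol = np.linalg.cholesky(target)
    x = rng.standard_normal((t, cfg.n_rois)) @ chol.T
    x = _ar1_smooth(x, cfg.ar_phi)
    ts = RoiTimeSeries(data=x, tr_s=cfg.tr_s, subject_id=subject_id, run_id=run_id)
    return ts, target


def make_cohort(cfg: SyntheticConfig) -> GroundTruthCohort:
    """Generate the full cohort: n_subjects x n_runs labelled runs plus
    ground-truth correlation targets."""
    subject_corrs: dict[str, np.ndarray] = {}
    run_corrs: dict[tuple[str, str], np.ndarray] = {}
    runs: list[RoiTimeSeries] = []
    for i, sigma in enumerate(make_subject_covariances(cfg)):
        sid = subject_label(i)
        subject_corrs[sid] = sigma
        for j in range(cfg.n_runs):
            rid = run_label(j)
            ts, target = simulate_run(sigma, cfg, sid, rid)
            run_corrs[(sid, rid)] = target
            runs.append(ts)
    return GroundTruthCohort(
        config=cfg, subject_corrs=subject_corrs, run_corrs=run_corrs, runs=runs
    )


def with_seed(cfg: SyntheticConfig, seed: int) -> SyntheticConfig:
    """Same generative conditions, different random stream."""
    return replace(cfg, seed=seed)
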