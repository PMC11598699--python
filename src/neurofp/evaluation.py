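"""Evaluation protocols: splits, identification metrics, statistics, sweeps.

Two splitting regimes are supported.  Leave-run-out (LRO) trains on a
subset of each subject's runs and tests on the remaining runs of the same
subjects — generalization across sessions.  Leave-subject-out (LSO) holds
out whole subjects — generalization to unseen identities, which only the
metric-learning model supports.

Identification from embeddings follows the nearest-neighbour rule: an
anchor is correctly identified when its closest positive (another run of
the same subject) is nearer than every negative (any run of any other
subject).  Chance level is therefore per-anchor
``n_positives / (n_candidates)`` and varies with the evaluation-set size.

Method comparisons use a two-sample permutation t-test (pooled-variance t,
label reshuffling, add-one p-value; exact enumeration when feasible).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.metrics import precision_recall_fscore_support

from .baseline import FCDatabase, baseline_accuracy, build_fc_database
from .core import IdentificationReport, RoiTimeSeries
from .models import (
    FULL,
    DlmTL,
    EmbeddingSet,
    ModelConfig,
    embed,
    train_dlm_ce,
    train_dlm_tl,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SplitPlan",
    "SweepResult",
    "make_lro_folds",
    "make_lso_folds",
    "identify_from_embeddings",
    "macro_metrics",
    "permutation_t_test",
    "run_lro_experiment",
    "run_lso_experiment",
    "sweep_segment_length",
    "sweep_split_ratio",
    "sweep_dataset_size",
    "split_ratio_fractions",
    "dataset_size_grid",
    "umap_project",
]


@dataclass(frozen=True)
class SplitPlan:
    """One train/test partition, by runs (LRO) or by subjects (LSO)."""

    mode: str  # "LRO" | "LSO"
    train: tuple[str, ...]
    test: tuple[str, ...]
    fold_id: int
    repetition_id: int
    seed: int

    def __post_init__(self) -> None:
        if self.mode not in ("LRO", "LSO"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if set(self.train) & set(self.test):
            raise ValueError("train and test overlap")
        if not self.train or not self.test:
            raise ValueError("both sides of a split must be non-empty")


@dataclass
class SweepResult:
    """Per-cell replicate accuracies for a sensitivity sweep.

    ``grid`` has one row per (cell, method, replicate) with the replicate
    accuracy; ``summary`` aggregates mean and standard deviation.
    ``tests`` optionally holds per-cell permutation-test results.
    """

    variable: str
    grid: pd.DataFrame
    tests: Optional[pd.DataFrame] = None
    meta: dict = field(default_factory=dict)

    @property
    def summary(self) -> pd.DataFrame:
        g = self.grid.groupby([self.variable, "method"])["accuracy"]
        out = g.agg(["mean", "std", "count"]).reset_index()
        return out.rename(columns={"count": "n_replicates"})


def make_lro_folds(
    runs: Sequence[str], n_reps: int = 10, base_seed: int = 0
) -> list[SplitPlan]:
    """All half/half run combinations, repeated.

    For 4 runs: C(4,2) = 6 combinations x ``n_reps`` = 60 plans, each with
    a distinct seed.
    """
    runs = sorted(runs)
    if len(runs) < 2:
        raise ValueError("LRO needs at least 2 runs")
    k = len(runs) // 2
    combos = list(itertools.combinations(runs, k))
    plans = []
    for rep in range(n_reps):
        for fold, train in enumerate(combos):
            test = tuple(r for r in runs if r not in train)
            plans.append(
                SplitPlan(
                    mode="LRO",
                    train=tuple(train),
                    test=test,
                    fold_id=fold,
                    repetition_id=rep,
                    seed=base_seed + rep * len(combos) + fold,
                )
            )
    return plans


def make_lso_folds(
    subjects: Sequence[str],
    n_folds: int = 6,
    n_reps: int = 10,
    rng: Optional[np.random.Generator] = None,
    base_seed: int = 0,
) -> list[SplitPlan]:
    """Shuffled k-fold partition of subjects, repeated.

    Each repetition reshuffles the subjects and partitions them into
    ``n_folds`` near-equal folds; each fold serves once as the test side.
    138 subjects with 6 folds give 115 train / 23 test.
    """
    subjects = sorted(subjects)
    if n_folds > len(subjects):
        raise ValueError("more folds than subjects")
    if rng is None:
        rng = np.random.default_rng(base_seed)
    plans = []
    for rep in range(n_reps):
        order = list(rng.permutation(subjects))
        folds = [list(f) for f in np.array_split(order, n_folds)]
        if any(len(f) < 2 for f in folds):
            raise ValueError("a fold has fewer than 2 subjects; identification undefined")
        for fold_id, test in enumerate(folds):
            train = [s for s in order if s not in set(test)]
            plans.append(
                SplitPlan(
                    mode="LSO",
                    train=tuple(train),
                    test=tuple(test),
                    fold_id=fold_id,
                    repetition_id=rep,
                    seed=base_seed + rep * n_folds + fold_id,
                )
            )
    return plans


def identify_from_embeddings(emb: EmbeddingSet) -> IdentificationReport:
    """Nearest-neighbour identification over an embedding set.

    An anchor succeeds when the minimum squared distance to a positive
    (same subject, different key) is smaller than the minimum distance to
    any negative.  The predicted label — used for the macro precision /
    recall / F1 — is the subject of the global nearest neighbour.
    """
    mat, subjects, keys = emb.matrix()
    subjects = np.asarray(subjects)
    singles = sorted({s for s in subjects if (subjects == s).sum() < 2})
    if singles:
        raise ValueError(f"subjects with a single embedding: {singles}")
    sq = (mat**2).sum(axis=1)
    dists = np.maximum(sq[:, None] + sq[None, :] - 2.0 * mat @ mat.T, 0.0)
    np.fill_diagonal(dists, np.inf)
    rows = []
    for i, key in enumerate(keys):
        same = subjects == subjects[i]
        same_i = same.copy()
        same_i[i] = False
        d_pos = dists[i, same_i].min()
        d_neg = dists[i, ~same].min()
        nearest = int(np.argmin(dists[i]))
        rows.append(
            {
                "query_subject_id": subjects[i],
                "query_run_id": "/".join(str(k) for k in key[1:]),
                "predicted_subject_id": subjects[nearest],
                "score": int(d_pos < d_neg),
            }
        )
    report = IdentificationReport(records=pd.DataFrame(rows))
    macro_metrics(report)
    return report


def macro_metrics(report: IdentificationReport) -> tuple[float, float, float]:
    """Macro-averaged precision, recall, F1 from the report's predicted
    labels; stored on the report and returned."""
    y_true = report.records["query_subject_id"].to_numpy()
    y_pred = report.records["predicted_subject_id"].to_numpy()
    labels = sorted(set(y_true))
    p, r, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average="macro", zero_division=0
    )
    report.precision, report.recall, report.f1 = float(p), float(r), float(f1)
    return float(p), float(r), float(f1)


def _pooled_t(sx, sxx, nx, sy, syy, ny):
    """Pooled-variance two-sample t from sufficient statistics (vectorized)."""
    mx = sx / nx
    my = sy / ny
    vx = sxx / nx - mx**2
    vy = syy / ny - my**2
    sp2 = (nx * vx + ny * vy) / (nx + ny - 2)
    denom = np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mx - my) / denom
    return t


def permutation_t_test(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = 100_000,
    rng: Optional[np.random.Generator] = None,
    paired: bool = False,
) -> tuple[float, float]:
    """Two-sided two-sample permutation t-test.

    The observed statistic is the pooled-variance t.  The null is built by
    reassigning the pooled values to groups of the original sizes; when the
    total number of distinct assignments is at most ``n_perm`` they are
    enumerated exhaustively (p = exceedance fraction), otherwise ``n_perm``
    random reassignments are drawn and the add-one convention
    ``p = (1 + #exceed) / (1 + n_perm)`` is used.  ``paired=True`` switches
    to sign-flipping of the per-pair differences (one-sample t).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need at least 2 values")
    if rng is None:
        rng = np.random.default_rng(0)
    if paired:
        if x.size != y.size:
            raise ValueError("paired test needs equal sample sizes")
        d = x - y
        t_obs = _one_sample_t(d)
        n = d.size
        if 2**n <= n_perm:
            signs = np.array(list(itertools.product([1.0, -1.0], repeat=n)))
            t_null = np.array([_one_sample_t(d * s) for s in signs])
            p = float(np.mean(np.abs(t_null) >= abs(t_obs) - 1e-12))
        else:
            flips = rng.choice([1.0, -1.0], size=(n_perm, n))
            t_null = np.array([_one_sample_t(d * s) for s in flips])
            exceed = int(np.sum(np.abs(t_null) >= abs(t_obs) - 1e-12))
            p = (1 + exceed) / (1 + n_perm)
        return float(t_obs), float(p)

    nx, ny = x.size, y.size
    pool = np.concatenate([x, y])
    if np.ptp(pool) == 0:
        # all values identical: no evidence either way
        return 0.0, 1.0
    t_obs = float(
        _pooled_t(x.sum(), (x**2).sum(), nx, y.sum(), (y**2).sum(), ny)
    )
    if not np.isfinite(t_obs):
        t_obs = math.copysign(math.inf, x.mean() - y.mean())
    total = special.comb(nx + ny, nx, exact=True)
    sq = pool**2
    tot_s, tot_ss = pool.sum(), sq.sum()
    if total <= n_perm:
        idx = np.array(list(itertools.combinations(range(nx + ny), nx)))
        sx = pool[idx].sum(axis=1)
        sxx = sq[idx].sum(axis=1)
        t_null = _pooled_t(sx, sxx, nx, tot_s - sx, tot_ss - sxx, ny)
        t_null = np.nan_to_num(t_null, nan=np.inf)
        p = float(np.mean(np.abs(t_null) >= abs(t_obs) - 1e-12))
    else:
        # vectorized random reassignment in chunks
        exceed = 0
        chunk = 20_000
        done = 0
        while done < n_perm:
            m = min(chunk, n_perm - done)
            u = rng.random((m, nx + ny))
            part = np.argpartition(u, nx, axis=1)[:, :nx]
            sx = pool[part].sum(axis=1)
            sxx = sq[part].sum(axis=1)
            t_null = _pooled_t(sx, sxx, nx, tot_s - sx, tot_ss - sxx, ny)
            t_null = np.nan_to_num(t_null, nan=np.inf)
            exceed += int(np.sum(np.abs(t_null) >= abs(t_obs) - 1e-12))
            done += m
        p = (1 + exceed) / (1 + n_perm)
    return t_obs, float(p)


def _one_sample_t(d: np.ndarray) -> float:
    sd = d.std(ddof=1)
    if sd == 0:
        return 0.0 if d.mean() == 0 else math.copysign(math.inf, d.mean())
    return float(d.mean() / (sd / math.sqrt(d.size)))


# ---------------------------------------------------------------------------
# Experiment runners


def _runs_by(runs: list[RoiTimeSeries]):
    by_run: dict[str, list[RoiTimeSeries]] = {}
    by_subject: dict[str, list[RoiTimeSeries]] = {}
    for ts in runs:
        by_run.setdefault(ts.run_id, []).append(ts)
        by_subject.setdefault(ts.subject_id, []).append(ts)
    return by_run, by_subject


def run_lro_experiment(
    runs: list[RoiTimeSeries],
    plan: SplitPlan,
    method: str,
    cfg: ModelConfig,
    rng: np.random.Generator,
) -> IdentificationReport:
    """Train on the plan's train runs, identify on the test runs.

    ``method`` is ``"ce"`` (softmax classification of test-run fingerprints)
    or ``"tl"`` (embedding nearest-neighbour identification over the test
    runs of all subjects).
    """
    if plan.mode != "LRO":
        raise ValueError("expected an LRO plan")
    train_runs = [ts for ts in runs if ts.run_id in set(plan.train)]
    test_runs = [ts for ts in runs if ts.run_id in set(plan.test)]
    if method == "ce":
        model = train_dlm_ce(train_runs, cfg, rng)
        from .connectivity import bandpass, fingerprint

        x = np.stack([fingerprint(bandpass(ts)).values for ts in test_runs])
        preds = model.predict(x)
        rows = [
            {
                "query_subject_id": ts.subject_id,
                "query_run_id": ts.run_id,
                "predicted_subject_id": pred,
                "score": int(pred == ts.subject_id),
            }
            for ts, pred in zip(test_runs, preds)
        ]
        report = IdentificationReport(records=pd.DataFrame(rows))
        macro_metrics(report)
        return report
    if method == "tl":
        model = train_dlm_tl(train_runs, cfg, rng)
        emb = embed(model, test_runs)
        return identify_from_embeddings(emb)
    raise ValueError(f"unknown method {method!r}")


def run_lso_experiment(
    runs: list[RoiTimeSeries],
    plan: SplitPlan,
    cfg: ModelConfig,
    rng: np.random.Generator,
) -> IdentificationReport:
    """Train the encoder on the plan's train subjects, identify the held-out
    subjects from their embeddings (all runs)."""
    if plan.mode != "LSO":
        raise ValueError("expected an LSO plan")
    train_set = set(plan.train)
    test_set = set(plan.test)
    train_runs = [ts for ts in runs if ts.subject_id in train_set]
    test_runs = [ts for ts in runs if ts.subject_id in test_set]
    model = train_dlm_tl(train_runs, cfg, rng)
    emb = embed(model, test_runs)
    return identify_from_embeddings(emb)


# ---------------------------------------------------------------------------
# Sensitivity sweeps


def _baseline_accuracy_for(runs: list[RoiTimeSeries]) -> float:
    from .baseline import baseline_all_pairs

    db = build_fc_database(runs)
    return baseline_all_pairs(db).accuracy


def sweep_segment_length(
    runs: list[RoiTimeSeries],
    lengths_s: Sequence,
    methods: Sequence[str] = ("baseline", "lro_ce", "lro_tl", "lso_tl"),
    n_reps: int = 10,
    cfg: Optional[ModelConfig] = None,
    base_seed: int = 0,
    lso_n_folds: int = 2,
) -> SweepResult:
    """Accuracy as a function of the augmentation segment length.

    For each length x deep method x replicate, a model is trained with that
    crop length and evaluated under its protocol (LRO folds cycle through
    the run combinations; LSO folds cycle through subject folds).  The
    correlation baseline uses full runs and is constant across lengths.
    Per length, each triplet-loss variant is compared against the LRO
    cross-entropy model with a permutation t-test.
    """
    if cfg is None:
        raise ValueError("a ModelConfig template is required")
    run_ids = sorted({ts.run_id for ts in runs})
    subjects = sorted({ts.subject_id for ts in runs})
    lro_plans = make_lro_folds(run_ids, n_reps=n_reps, base_seed=base_seed)
    lso_plans = make_lso_folds(
        subjects, n_folds=lso_n_folds, n_reps=n_reps, base_seed=base_seed
    )
    base_acc = _baseline_accuracy_for(runs) if "baseline" in methods else None
    rows = []
    for length in lengths_s:
        seg = FULL if length == FULL else float(length)
        for rep in range(n_reps):
            if "baseline" in methods:
                rows.append(
                    {
                        "segment_length_s": str(length),
                        "method": "baseline",
                        "replicate": rep,
                        "accuracy": base_acc,
                    }
                )
            lro_plan = lro_plans[rep % len(lro_plans)]
            lso_plan = lso_plans[rep % len(lso_plans)]
            from dataclasses import replace

            cell_cfg = replace(cfg, segment_length_s=seg, seed=base_seed + rep)
            for method in methods:
                if method == "baseline":
                    continue
                rng = np.random.default_rng(
                    np.random.SeedSequence([base_seed, rep, hash(str(length)) % 2**31])
                )
                if method == "lro_ce":
                    rep_report = run_lro_experiment(runs, lro_plan, "ce", cell_cfg, rng)
                elif method == "lro_tl":
                    rep_report = run_lro_experiment(runs, lro_plan, "tl", cell_cfg, rng)
                elif method == "lso_tl":
                    rep_report = run_lso_experiment(runs, lso_plan, cell_cfg, rng)
                else:
                    raise ValueError(f"unknown method {method!r}")
                rows.append(
                    {
                        "segment_length_s": str(length),
                        "method": method,
                        "replicate": rep,
                        "accuracy": rep_report.accuracy,
                    }
                )
    grid = pd.DataFrame(rows)
    tests = []
    if "lro_ce" in methods:
        for length in grid["segment_length_s"].unique():
            cell = grid[grid["segment_length_s"] == length]
            ce = cell[cell["method"] == "lro_ce"]["accuracy"].to_numpy()
            for tl_method in ("lro_tl", "lso_tl"):
                if tl_method not in set(cell["method"]):
                    continue
                tl = cell[cell["method"] == tl_method]["accuracy"].to_numpy()
                t, p = permutation_t_test(
                    tl, ce, n_perm=100_000, rng=np.random.default_rng(base_seed)
                )
                tests.append(
                    {
                        "segment_length_s": length,
                        "comparison": f"{tl_method} vs lro_ce",
                        "t": t,
                        "p": p,
                    }
                )
    return SweepResult(
        variable="segment_length_s",
        grid=grid,
        tests=pd.DataFrame(tests) if tests else None,
    )


def split_ratio_fractions(n_steps: int = 19) -> np.ndarray:
    """Training-set fractions from 5% to 95%, evenly spaced."""
    return np.linspace(0.05, 0.95, n_steps)


def sweep_split_ratio(
    runs: list[RoiTimeSeries],
    fractions: Optional[Sequence[float]] = None,
    n_reps: int = 10,
    segment_s: float = 270.0,
    cfg: Optional[ModelConfig] = None,
    base_seed: int = 0,
) -> SweepResult:
    """LSO accuracy versus the train/validation subject split ratio.

    Per fraction and replicate: subjects are shuffled, the first
    ``round(fraction * n)`` train the encoder, the rest are identified
    from their embeddings.  The correlation baseline is evaluated on the
    same validation subjects.  Infeasible fractions (fewer than 2 subjects
    on either side) are skipped with a warning.
    """
    if cfg is None:
        raise ValueError("a ModelConfig template is required")
    if fractions is None:
        fractions = split_ratio_fractions()
    from dataclasses import replace

    subjects = sorted({ts.subject_id for ts in runs})
    n = len(subjects)
    rows = []
    for frac in fractions:
        n_train = int(round(frac * n))
        n_val = n - n_train
        if n_train < 2 or n_val < 2:
            logger.warning(
                "skipping fraction %.2f: %d train / %d validation subjects",
                frac, n_train, n_val,
            )
            continue
        for rep in range(n_reps):
            rng = np.random.default_rng(
                np.random.SeedSequence([base_seed, rep, int(round(frac * 1000))])
            )
            order = list(rng.permutation(subjects))
            plan = SplitPlan(
                mode="LSO",
                train=tuple(order[:n_train]),
                test=tuple(order[n_train:]),
                fold_id=0,
                repetition_id=rep,
                seed=base_seed + rep,
            )
            cell_cfg = replace(cfg, segment_length_s=segment_s, seed=base_seed + rep)
            report = run_lso_experiment(runs, plan, cell_cfg, rng)
            rows.append(
                {
                    "train_fraction": float(frac),
                    "method": "lso_tl",
                    "replicate": rep,
                    "accuracy": report.accuracy,
                }
            )
            val_runs = [ts for ts in runs if ts.subject_id in set(plan.test)]
            rows.append(
                {
                    "train_fraction": float(frac),
                    "method": "baseline",
                    "replicate": rep,
                    "accuracy": _baseline_accuracy_for(val_runs),
                }
            )
    return SweepResult(variable="train_fraction", grid=pd.DataFrame(rows))


def dataset_size_grid(
    start: tuple[int, int] = (92, 46), floor: tuple[int, int] = (8, 4)
) -> list[tuple[int, int]]:
    """(train, validation) subject counts, shrinking by 10% per step.

    The train count is multiplied by 0.9 and rounded at every step until
    the floor is reached; validation stays at half the train count
    (2:1 ratio).  Endpoints are exactly ``start`` and ``floor``.
    """
    grid = []
    t = start[0]
    while t > floor[0]:
        grid.append((t, max(floor[1], int(round(t / 2)))))
        nxt = int(round(t * 0.9))
        t = nxt if nxt < t else t - 1
    grid.append(floor)
    # first cell must match the requested start exactly
    grid[0] = start
    return grid


def sweep_dataset_size(
    runs: list[RoiTimeSeries],
    grid: Optional[Sequence[tuple[int, int]]] = None,
    n_reps: int = 10,
    segment_s: float = 270.0,
    cfg: Optional[ModelConfig] = None,
    base_seed: int = 0,
) -> SweepResult:
    """LSO accuracy versus cohort size at a fixed 2:1 train:validation ratio.

    Per (train, validation) cell and replicate, that many subjects are
    subsampled from the cohort, the encoder is trained on the train
    subjects and evaluated on the validation subjects; the correlation
    baseline runs on the same validation subjects.
    """
    if cfg is None:
        raise ValueError("a ModelConfig template is required")
    if grid is None:
        grid = dataset_size_grid()
    from dataclasses import replace

    subjects = sorted({ts.subject_id for ts in runs})
    rows = []
    for n_train, n_val in grid:
        if n_train + n_val > len(subjects):
            raise ValueError(
                f"cell ({n_train}, {n_val}) needs {n_train + n_val} subjects, "
                f"cohort has {len(subjects)}"
            )
        for rep in range(n_reps):
            rng = np.random.default_rng(
                np.random.SeedSequence([base_seed, rep, n_train, n_val])
            )
            order = list(rng.permutation(subjects))
            plan = SplitPlan(
                mode="LSO",
                train=tuple(order[:n_train]),
                test=tuple(order[n_train : n_train + n_val]),
                fold_id=0,
                repetition_id=rep,
                seed=base_seed + rep,
            )
            cell_cfg = replace(cfg, segment_length_s=segment_s, seed=base_seed + rep)
            subset = [
                ts for ts in runs if ts.subject_id in set(plan.train) | set(plan.test)
            ]
            report = run_lso_experiment(subset, plan, cell_cfg, rng)
            rows.append(
                {
                    "n_train_subjects": n_train,
                    "n_val_subjects": n_val,
                    "cohort_size": n_train + n_val,
                    "method": "lso_tl",
                    "replicate": rep,
                    "accuracy": report.accuracy,
                }
            )
            val_runs = [ts for ts in runs if ts.subject_id in set(plan.test)]
            rows.append(
                {
                    "n_train_subjects": n_train,
                    "n_val_subjects": n_val,
                    "cohort_size": n_train + n_val,
                    "method": "baseline",
                    "replicate": rep,
                    "accuracy": _baseline_accuracy_for(val_runs),
                }
            )
    res = SweepResult(variable="cohort_size", grid=pd.DataFrame(rows))
    res.meta["grid"] = list(grid)
    return res


def umap_project(
    emb: EmbeddingSet,
    seed: int = 0,
    n_neighbors: int = 15,
    learning_rate: float = 1.0,
) -> pd.DataFrame:
    """2-D UMAP projection of the embeddings (euclidean metric).

    Returns one row per embedding with subject/run labels and the two
    coordinates, for cluster visualization.
    """
    import umap

    mat, subjects, keys = emb.matrix()
    if mat.shape[0] < n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors+1 = {n_neighbors + 1} embeddings, "
            f"got {mat.shape[0]}"
        )
    reducer = umap.UMAP(
        n_neighbors=n_neighbors,
        n_components=2,
        metric="euclidean",
        learning_rate=learning_rate,
        random_state=seed,
    )
    coords = reducer.fit_transform(mat)
    return pd.DataFrame(
        {
            "subject_id": subjects,
            "run_id": ["/".join(str(k) for k in key[1:]) for key in keys],
            "umap_1": coords[:, 0],
            "umap_2": coords[:, 1],
        }
    )
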