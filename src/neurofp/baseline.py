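"""Correlation-based identification baseline.

The classic fingerprinting reference: each query-session FC vector is
compared against every target-session vector by Pearson correlation, and
the predicted identity is the subject owning the vector with the highest
absolute correlation.  Identification is scored 1 when the predicted
subject matches the query subject, 0 otherwise; accuracy is the mean
score over subjects and comparisons.

By default the match uses |r| (so an anti-correlated fingerprint of the
same subject still matches); ``signed=True`` switches to raw r for the
variant some earlier studies use.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import bandpass, fingerprint
from .core import FCVector, IdentificationReport, RoiTimeSeries

__all__ = [
    "FCDatabase",
    "build_fc_database",
    "match_query",
    "baseline_accuracy",
    "baseline_all_pairs",
]


@dataclass
class FCDatabase:
    """Mapping (subject_id, run_id) -> FC vector, all of equal length."""

    vectors: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def add(self, vec: FCVector | np.ndarray, subject_id: str | None = None,
            run_id: str | None = None) -> None:
        if isinstance(vec, FCVector):
            subject_id = vec.subject_id
            run_id = vec.run_id
            values = vec.values
        else:
            if subject_id is None or run_id is None:
                raise ValueError("raw arrays need explicit subject_id and run_id")
            values = np.asarray(vec, dtype=float).ravel()
        if self.vectors and values.size != self.vector_length:
            raise ValueError(
                f"vector length {values.size} != database length {self.vector_length}"
            )
        key = (subject_id, run_id)
        if key in self.vectors:
            raise ValueError(f"duplicate entry {key}")
        self.vectors[key] = values

    @property
    def vector_length(self) -> int:
        return next(iter(self.vectors.values())).size

    @property
    def subjects(self) -> list[str]:
        return sorted({s for s, _ in self.vectors})

    @property
    def run_ids(self) -> list[str]:
        return sorted({r for _, r in self.vectors})

    def runs_for(self, subject_id: str) -> list[str]:
        return sorted(r for s, r in self.vectors if s == subject_id)

    def __len__(self) -> int:
        return len(self.vectors)


def build_fc_database(
    runs: list[RoiTimeSeries],
    apply_bandpass: bool = True,
    band_hz: tuple[float, float] = (0.01, 0.1),
) -> FCDatabase:
    """Full-run fingerprints for every run, optionally bandpassed first."""
    db = FCDatabase()
    for ts in runs:
        if apply_bandpass:
            ts = bandpass(ts, *band_hz)
        db.add(fingerprint(ts))
    return db


def _pearson_to_targets(q: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Pearson r between one query vector and each row of ``targets``."""
    qc = q - q.mean()
    qn = np.linalg.norm(qc)
    if qn == 0:
        raise ValueError("query vector has zero variance")
    tc = targets - targets.mean(axis=1, keepdims=True)
    tn = np.linalg.norm(tc, axis=1)
    if np.any(tn == 0):
        raise ValueError("a target vector has zero variance")
    return (tc @ qc) / (tn * qn)


def match_query(
    q: FCVector | np.ndarray,
    targets: FCDatabase,
    signed: bool = False,
) -> tuple[str, pd.DataFrame]:
    """Predict the subject whose target vector best matches ``q``.

    Returns the predicted subject and the full similarity table sorted by
    (subject_id, run_id).  Exact ties on the match score are broken by the
    first entry in that sorted order, with a warning.
    """
    if not targets.vectors:
        raise ValueError("target database is empty")
    values = q.values if isinstance(q, FCVector) else np.asarray(q, dtype=float).ravel()
    keys = sorted(targets.vectors.keys())
    mat = np.stack([targets.vectors[k] for k in keys])
    r = _pearson_to_targets(values, mat)
    score = r if signed else np.abs(r)
    best = int(np.argmax(score))
    ties = np.flatnonzero(score == score[best])
    if ties.size > 1:
        warnings.warn(
            f"tie between {[keys[i] for i in ties]}; keeping first in sorted order",
            stacklevel=2,
        )
    table = pd.DataFrame(
        {
            "subject_id": [k[0] for k in keys],
            "run_id": [k[1] for k in keys],
            "r": r,
            "match_score": score,
        }
    )
    return keys[best][0], table


def _report_from_rows(rows: list[dict]) -> IdentificationReport:
    return IdentificationReport(records=pd.DataFrame(rows))


def baseline_accuracy(
    db: FCDatabase,
    query_run: str,
    target_runs: set[str] | list[str],
    signed: bool = False,
) -> IdentificationReport:
    """One identification pass: every subject's ``query_run`` vector against
    all subjects' ``target_runs`` vectors."""
    target_runs = set(target_runs)
    if query_run in target_runs:
        raise ValueError(f"query run {query_run!r} must not be among the targets")
    missing = [
        s
        for s in db.subjects
        if query_run not in db.runs_for(s)
        or not target_runs.intersection(db.runs_for(s))
    ]
    if missing:
        raise ValueError(
            f"subjects {missing} lack the query run {query_run!r} or any of "
            f"the target runs {sorted(target_runs)}"
        )
    targets = FCDatabase(
        vectors={
            (s, r): v for (s, r), v in db.vectors.items() if r in target_runs
        }
    )
    rows = []
    for s in db.subjects:
        pred, _ = match_query(db.vectors[(s, query_run)], targets, signed=signed)
        rows.append(
            {
                "query_subject_id": s,
                "query_run_id": query_run,
                "predicted_subject_id": pred,
                "score": int(pred == s),
            }
        )
    return _report_from_rows(rows)


def baseline_all_pairs(
    db: FCDatabase,
    signed: bool = False,
    multi_target: bool = False,
) -> IdentificationReport:
    """Average identification over all query/target session combinations.

    Default: all ordered pairs of distinct single sessions (12 comparisons
    for 4 runs).  ``multi_target=True`` instead pools all other sessions as
    targets for each query session (4 comparisons for 4 runs).
    """
    run_ids = db.run_ids
    if any(len(db.runs_for(s)) < 2 for s in db.subjects):
        raise ValueError("every subject needs at least 2 runs")
    reports = []
    pair_rows = []
    if multi_target:
        plans = [(q, set(run_ids) - {q}) for q in run_ids]
    else:
        plans = [(q, {t}) for q, t in itertools.permutations(run_ids, 2)]
    for query_run, target_runs in plans:
        rep = baseline_accuracy(db, query_run, target_runs, signed=signed)
        reports.append(rep)
        pair_rows.append(
            {
                "query_run_id": query_run,
                "target_run_ids": ",".join(sorted(target_runs)),
                "accuracy": rep.accuracy,
            }
        )
    combined = _report_from_rows(
        [row for rep in reports for row in rep.records.to_dict("records")]
    )
    combined.extra["per_comparison"] = pd.DataFrame(pair_rows)
    return combined
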