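"""Readers and writers for cohort, fingerprint, report and model artifacts.

All tabular artifacts are UTF-8 comma-separated text with a header row;
files carry a leading ``# schema:`` comment naming their schema version so
stages can validate their inputs.  Model weights are stored as an ``.npz``
archive next to a plain-text JSON architecture description, so embeddings
remain recomputable without unpickling anything.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import nn
from .connectivity import edge_names
from .core import IdentificationReport, RoiTimeSeries
from .models import DlmCE, DlmTL, ModelConfig
from .synthetic import GroundTruthCohort, SyntheticConfig

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_fc_table",
    "read_fc_table",
    "write_report",
    "read_report",
    "save_model",
    "load_model",
]

SCHEMAS = {
    "manifest": "neurofp/manifest v1",
    "timeseries": "neurofp/timeseries v1",
    "fc": "neurofp/fc v1",
    "report": "neurofp/report v1",
}


def _write_csv(df: pd.DataFrame, path: Path, schema: str, meta: dict | None = None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# schema: {schema}\n")
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


def _read_csv(path: Path, schema: str) -> tuple[pd.DataFrame, dict]:
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    n_comment = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            break
        n_comment = i + 1
        body = line[1:].strip()
        if ":" in body:
            key, _, value = body.partition(":")
            meta[key.strip()] = value.strip()
    found = meta.get("schema")
    if found != schema:
        raise ValueError(
            f"{path}: expected schema {schema!r}, found {found!r} (line 1)"
        )
    from io import StringIO

    try:
        df = pd.read_csv(
            StringIO("".join(lines[n_comment:])), float_precision="round_trip"
        )
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise ValueError(f"{path}: malformed table after line {n_comment}: {exc}")
    return df, meta


def write_cohort(cohort: GroundTruthCohort, out_dir: str | Path) -> Path:
    """Write one time-series table per run plus a manifest and config echo.

    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = [f"roi_{i:03d}" for i in range(cohort.config.n_rois)]
    rows = []
    for ts in cohort.runs:
        fname = f"{ts.subject_id}_{ts.run_id}.csv"
        _write_csv(
            pd.DataFrame(ts.data, columns=names),
            out_dir / fname,
            SCHEMAS["timeseries"],
            {"subject_id": ts.subject_id, "run_id": ts.run_id, "tr_s": ts.tr_s},
        )
        rows.append(
            {
                "subject_id": ts.subject_id,
                "run_id": ts.run_id,
                "path": fname,
                "tr_s": ts.tr_s,
            }
        )
    manifest = out_dir / "manifest.csv"
    _write_csv(
        pd.DataFrame(rows),
        manifest,
        SCHEMAS["manifest"],
        {"n_rois": cohort.config.n_rois, "seed": cohort.config.seed},
    )
    with open(out_dir / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(cohort.config), fh, sort_keys=False)
    return manifest


def read_cohort(manifest_path: str | Path) -> list[RoiTimeSeries]:
    """Load every run listed in a manifest, validating shapes as we go."""
    manifest_path = Path(manifest_path)
    df, _ = _read_csv(manifest_path, SCHEMAS["manifest"])
    required = {"subject_id", "run_id", "path", "tr_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{manifest_path}: manifest missing columns {sorted(missing)}")
    dup = df.duplicated(subset=["subject_id", "run_id"])
    if dup.any():
        raise ValueError(
            f"{manifest_path}: duplicate (subject_id, run_id) rows at "
            f"{df.index[dup].tolist()}"
        )
    if df["tr_s"].nunique() != 1:
        raise ValueError(f"{manifest_path}: mixed tr_s values {sorted(df['tr_s'].unique())}")
    runs = []
    shape: Optional[tuple[int, int]] = None
    for row in df.itertuples():
        path = manifest_path.parent / str(row.path)
        if not path.exists():
            raise FileNotFoundError(
                f"manifest row {row.Index} ({row.subject_id}/{row.run_id}): "
                f"missing file {path}"
            )
        table, _ = _read_csv(path, SCHEMAS["timeseries"])
        data = table.to_numpy(dtype=float)
        if np.isnan(data).any():
            raise ValueError(f"{path}: NaN values in time-series table")
        if shape is None:
            shape = data.shape
        elif data.shape[1] != shape[1]:
            raise ValueError(
                f"{path}: {data.shape[1]} channels, but earlier runs have "
                f"{shape[1]} — mixed shapes {data.shape} vs {shape}"
            )
        runs.append(
            RoiTimeSeries(
                data=data,
                tr_s=float(row.tr_s),
                subject_id=str(row.subject_id),
                run_id=str(row.run_id),
            )
        )
    return runs


def write_fc_table(vectors: dict[tuple[str, str], np.ndarray], n_rois: int,
                   path: str | Path) -> None:
    """One row per (subject, run), columns named ``e_{i}_{j}``."""
    keys = sorted(vectors.keys())
    df = pd.DataFrame(
        np.stack([vectors[k] for k in keys]), columns=edge_names(n_rois)
    )
    df.insert(0, "subject_id", [k[0] for k in keys])
    df.insert(1, "run_id", [k[1] for k in keys])
    _write_csv(df, Path(path), SCHEMAS["fc"], {"n_rois": n_rois})


def read_fc_table(path: str | Path) -> tuple[dict[tuple[str, str], np.ndarray], int]:
    df, meta = _read_csv(Path(path), SCHEMAS["fc"])
    n_rois = int(meta["n_rois"])
    edge_cols = [c for c in df.columns if c.startswith("e_")]
    vectors = {
        (str(r.subject_id), str(r.run_id)): df.loc[r.Index, edge_cols].to_numpy(float)
        for r in df.itertuples()
    }
    return vectors, n_rois


def write_report(report: IdentificationReport, path: str | Path) -> None:
    """Per-query records with summary statistics in the header comments."""
    meta = {"accuracy": repr(report.accuracy)}
    for name in ("precision", "recall", "f1"):
        value = getattr(report, name)
        if value is not None:
            meta[name] = repr(value)
    if report.replicates is not None:
        meta["replicates"] = json.dumps(list(map(float, report.replicates)))
    _write_csv(report.records, Path(path), SCHEMAS["report"], meta)


def read_report(path: str | Path) -> IdentificationReport:
    df, meta = _read_csv(Path(path), SCHEMAS["report"])
    report = IdentificationReport(
        records=df,
        precision=float(meta["precision"]) if "precision" in meta else None,
        recall=float(meta["recall"]) if "recall" in meta else None,
        f1=float(meta["f1"]) if "f1" in meta else None,
        replicates=(
            np.array(json.loads(meta["replicates"])) if "replicates" in meta else None
        ),
    )
    stored = float(meta["accuracy"])
    if abs(stored - report.accuracy) > 1e-9:
        raise ValueError(
            f"{path}: stored accuracy {stored} disagrees with records "
            f"({report.accuracy})"
        )
    return report


def save_model(model: DlmCE | DlmTL, path: str | Path) -> None:
    """Weights to ``<path>.npz``, architecture to ``<path>.json``."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    layers = list(model.backbone.layers)
    if isinstance(model, DlmCE):
        layers.append(model.head)
    for i, layer in enumerate(layers):
        for j, p in enumerate(layer.params()):
            arrays[f"layer{i}_param{j}"] = p
        if isinstance(layer, nn.BatchNorm):
            arrays[f"layer{i}_running_mean"] = layer.running_mean
            arrays[f"layer{i}_running_var"] = layer.running_var
    np.savez(path.with_suffix(".npz"), **arrays)
    desc = {
        "kind": "dlm_ce" if isinstance(model, DlmCE) else "dlm_tl",
        "config": asdict(model.config),
        "loss_trace": list(map(float, model.loss_trace)),
    }
    if isinstance(model, DlmCE):
        desc["subjects"] = model.subjects
    else:
        desc["val_loss_trace"] = list(map(float, model.val_loss_trace))
        desc["best_epoch"] = model.best_epoch
    with open(path.with_suffix(".json"), "w", encoding="utf-8") as fh:
        json.dump(desc, fh, indent=2)


def load_model(path: str | Path) -> DlmCE | DlmTL:
    path = Path(path)
    with open(path.with_suffix(".json"), encoding="utf-8") as fh:
        desc = json.load(fh)
    cfg = ModelConfig(**desc["config"])
    rng = np.random.default_rng(0)
    from .models import _build_backbone

    backbone = _build_backbone(cfg, rng)
    if desc["kind"] == "dlm_ce":
        head = nn.Dense(cfg.hidden_2, len(desc["subjects"]), rng)
        model: DlmCE | DlmTL = DlmCE(
            backbone=backbone,
            head=head,
            subjects=list(desc["subjects"]),
            config=cfg,
            loss_trace=desc["loss_trace"],
        )
        layers = list(backbone.layers) + [head]
    else:
        model = DlmTL(
            backbone=backbone,
            config=cfg,
            loss_trace=desc["loss_trace"],
            val_loss_trace=desc.get("val_loss_trace", []),
            best_epoch=desc.get("best_epoch"),
        )
        layers = list(backbone.layers)
    with np.load(path.with_suffix(".npz")) as arrays:
        for i, layer in enumerate(layers):
            for j, p in enumerate(layer.params()):
                p[...] = arrays[f"layer{i}_param{j}"]
            if isinstance(layer, nn.BatchNorm):
                layer.running_mean[...] = arrays[f"layer{i}_running_mean"]
                layer.running_var[...] = arrays[f"layer{i}_running_var"]
    return model
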