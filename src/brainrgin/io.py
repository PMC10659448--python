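"""On-disk formats: matrices, manifests, graph bundles, cohort export.

Layouts
-------
*Matrix files* — one ROI-by-time (or ROI-by-ROI) numeric matrix per
subject, as delimited text (``.csv`` comma, ``.tsv`` tab, ``.txt``
whitespace, no header) or binary ``.npy``.

*Manifest* — a CSV with one row per subject: ``subject_id``, ``path``
(matrix file, relative paths resolved against the manifest's folder),
``score``, optional ``split`` (train/val/test) and any further columns
treated as covariates.

*Graph bundle* — ``<subject_id>.npz`` per subject holding
``node_features``, ``adjacency``, ``edges``, ``edge_weights``,
``roi_index`` plus a ``graphs_manifest.csv`` carrying scores/covariates
forward.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .graph_construction import FNCGraph, FNCMatrix, ROITimeSeries

__all__ = [
    "load_matrix",
    "save_matrix",
    "read_manifest",
    "load_timeseries",
    "load_fnc",
    "save_graph",
    "load_graph",
    "export_cohort",
]

_DELIMS = {".csv": ",", ".tsv": "\t", ".txt": None}


def load_matrix(path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".npy":
        return np.asarray(np.load(path), dtype=np.float64)
    if path.suffix in _DELIMS:
        return np.loadtxt(path, delimiter=_DELIMS[path.suffix], ndmin=2)
    raise ValueError(f"unsupported matrix format: {path.suffix}")


def save_matrix(values: np.ndarray, path) -> None:
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, np.asarray(values, dtype=np.float64))
    elif path.suffix in _DELIMS:
        np.savetxt(path, values, delimiter=_DELIMS[path.suffix] or " ")
    else:
        raise ValueError(f"unsupported matrix format: {path.suffix}")


def read_manifest(path) -> pd.DataFrame:
    """Manifest CSV with ``path`` resolved relative to its directory."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"subject_id", "path"}
    if not required <= set(df.columns):
        raise ValueError(f"manifest needs columns {sorted(required)}")
    df["subject_id"] = df["subject_id"].astype(str)
    df["path"] = [
        str(p) if Path(p).is_absolute() else str(path.parent / p) for p in df["path"]
    ]
    return df


def load_timeseries(path, subject_id: str = "") -> ROITimeSeries:
    return ROITimeSeries(load_matrix(path), subject_id=subject_id)


def load_fnc(path, subject_id: str = "") -> FNCMatrix:
    return FNCMatrix(load_matrix(path), subject_id=subject_id)


def save_graph(graph: FNCGraph, path) -> None:
    np.savez(
        path,
        node_features=graph.node_features,
        adjacency=graph.adjacency,
        edges=graph.edges,
        edge_weights=graph.edge_weights,
        roi_index=graph.roi_index,
        roi_labels=np.array(graph.roi_labels),
        subject_id=np.array(graph.subject_id),
    )


def load_graph(path) -> FNCGraph:
    with np.load(path, allow_pickle=False) as data:
        return FNCGraph(
            node_features=data["node_features"],
            adjacency=data["adjacency"],
            edges=data["edges"],
            edge_weights=data["edge_weights"],
            roi_index=data["roi_index"],
            roi_labels=[str(x) for x in data["roi_labels"]],
            subject_id=str(data["subject_id"]),
        )


def export_cohort(cohort, out_dir, fmt: str = "csv") -> Path:
    """Write a synthetic cohort as matrix files + manifest + ground truth.

    Produces the same layout :func:`read_manifest` consumes (round-trip
    tested), plus ``truth.json`` with the planted ROIs, split and seed.
    """
    from .synthetic_data import default_split  # local import, no cycle at module load

    out = Path(out_dir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    split = default_split(len(cohort))
    split_col = np.empty(len(cohort), dtype=object)
    for name, idx in split.items():
        split_col[idx] = name

    rows = []
    for m, ts in enumerate(cohort.timeseries):
        rel = f"timeseries/{ts.subject_id}.{fmt}"
        save_matrix(ts.values, out / rel)
        rows.append(
            {
                "subject_id": ts.subject_id,
                "path": rel,
                "score": cohort.observed_scores[m],
                "age": cohort.covariates["age"].iloc[m],
                "site": cohort.covariates["site"].iloc[m],
                "split": split_col[m],
            }
        )
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    truth = {
        "planted_rois": [int(r) for r in cohort.planted_rois],
        "seed": int(cohort.seed),
        "true_scores": [float(x) for x in cohort.true_scores],
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(cohort.config).items()
        },
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    return out / "manifest.csv"
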