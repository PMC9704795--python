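"""File formats: TSV tables, JSON metrics, matrix containers, cohort layout.

All tabular artifacts are plain TSV and all metrics JSON.  Matrices go into
one of two containers chosen by extension: ``.npy`` (portable NumPy binary,
the default for per-subject connectomes) or ``.tsv`` (text, ``%.17g`` so
float64 round-trips exactly).  Every matrix file carries a ``<file>.meta.json``
sidecar with its kind tag, node count and provenance metadata; loading into a
typed slot checks the tag.

Cohort directory layout::

    subjects.tsv          subject_id, age, sex, education, test_01..test_16
    parcellation.tsv      node_id, network, lobe, hemisphere
    truth.json            generating parameters (synthetic cohorts)
    timeseries/sub-*.npy  node x time matrices
    sc/sub-*.npy          streamline-weight matrices
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .matrices import ConnectivityMatrix
from .parcellation import validate_parcellation
from .synthetic import GroundTruth, SyntheticCohort


def save_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def load_json(path: str | Path):
    return json.loads(Path(path).read_text())


def save_table(path: str | Path, table: pd.DataFrame, index: bool = True) -> None:
    table.to_csv(path, sep="\t", index=index)


def load_table(path: str | Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def save_matrix(
    path: str | Path,
    values: np.ndarray | ConnectivityMatrix,
    kind: str | None = None,
    extra_meta: dict | None = None,
) -> None:
    """Write a matrix plus its metadata sidecar; format chosen by extension."""
    path = Path(path)
    meta: dict = dict(extra_meta or {})
    if isinstance(values, ConnectivityMatrix):
        meta.update(kind=values.kind, log_transformed=values.log_transformed, **values.meta)
        arr = values.values
    else:
        arr = np.asarray(values, dtype=float)
        if kind is not None:
            meta["kind"] = kind
    meta["shape"] = list(arr.shape)
    if path.suffix == ".npy":
        np.save(path, arr)
    elif path.suffix == ".tsv":
        np.savetxt(path, arr, fmt="%.17g", delimiter="\t")
    else:
        raise ValueError(f"unsupported matrix extension {path.suffix!r} (use .npy or .tsv)")
    save_json(path.with_suffix(path.suffix + ".meta.json"), meta)


def load_matrix(
    path: str | Path, expect_kind: str | None = None
) -> tuple[np.ndarray, dict]:
    """Read a matrix and its sidecar; verifies the kind tag when expected."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"matrix file not found: {path}")
    if path.suffix == ".npy":
        arr = np.load(path)
    elif path.suffix == ".tsv":
        arr = np.loadtxt(path, delimiter="\t", ndmin=2)
    else:
        raise ValueError(f"unsupported matrix extension {path.suffix!r}")
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = load_json(meta_path) if meta_path.exists() else {}
    if expect_kind is not None:
        found = meta.get("kind")
        if found != expect_kind:
            raise ValueError(f"{path}: kind tag {found!r} does not match expected {expect_kind!r}")
    if meta.get("shape") and list(arr.shape) != meta["shape"]:
        raise ValueError(f"{path}: shape {list(arr.shape)} does not match sidecar {meta['shape']}")
    return arr, meta


def load_connectivity(path: str | Path, expect_kind: str) -> ConnectivityMatrix:
    arr, meta = load_matrix(path, expect_kind=expect_kind)
    return ConnectivityMatrix(
        arr, expect_kind, log_transformed=bool(meta.get("log_transformed", False))
    )


def save_parcellation(path: str | Path, parc: pd.DataFrame) -> None:
    validate_parcellation(parc)
    parc.to_csv(path, sep="\t", index=False)


def load_parcellation(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"parcellation file not found: {path}")
    parc = pd.read_csv(path, sep="\t")
    validate_parcellation(parc)
    return parc


def save_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    (out / "sc").mkdir(parents=True, exist_ok=True)
    save_table(out / "subjects.tsv", cohort.subjects)
    save_parcellation(out / "parcellation.tsv", cohort.parcellation)
    save_json(out / "truth.json", {"seed": cohort.seed, **cohort.truth.to_dict()})
    for sid, ts, sc in zip(cohort.subjects.index, cohort.timeseries, cohort.sc_weights):
        save_matrix(out / "timeseries" / f"{sid}.npy", ts, kind=None)
        save_matrix(out / "sc" / f"{sid}.npy", sc, kind=None)
    return out


def load_cohort(in_dir: str | Path) -> SyntheticCohort:
    src = Path(in_dir)
    parc = load_parcellation(src / "parcellation.tsv")
    subjects = load_table(src / "subjects.tsv")
    truth_doc = load_json(src / "truth.json")
    seed = truth_doc.pop("seed", -1)
    truth = GroundTruth.from_dict(truth_doc)
    ts, sc = [], []
    for sid in subjects.index:
        ts.append(load_matrix(src / "timeseries" / f"{sid}.npy")[0])
        sc.append(load_matrix(src / "sc" / f"{sid}.npy")[0])
    return SyntheticCohort(subjects, ts, sc, parc, truth, seed)
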