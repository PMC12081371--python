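"""Point-cloud file I/O, cleanup, normalization and dataset splitting.

Formats are deliberately minimal and text-only: ASCII XYZ (one ``x y z``
triple per line) and ASCII PLY with an ``element vertex`` carrying float
``x, y, z`` properties.  Gesture labels ride along in PLY header comments
(``comment class_id N`` / ``comment subject_id N``) because PLY has no
standard label slot.

The interactive cleanup step used on real recordings (manually segmenting
away non-hand returns) is replaced by an automated statistical outlier
filter: a point is dropped when its mean distance to its k nearest
neighbors is more than ``sd_mult`` standard deviations above the cloud
average of that statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .hand import LabeledCloud

__all__ = [
    "CloudFormatError",
    "DatasetSplit",
    "read_xyz",
    "write_xyz",
    "read_ply",
    "write_ply",
    "remove_outliers",
    "normalize_cloud",
    "split_dataset",
    "write_manifest",
    "read_manifest",
]


class CloudFormatError(ValueError):
    """Malformed point-cloud file; message names the offending line."""


def _parse_rows(lines, n_expected=None, path="", first_line_no=1):
    rows = []
    for offset, line in enumerate(lines):
        stripped = line.strip()
        if not stripped:
            continue
        fields = stripped.split()
        line_no = first_line_no + offset
        if len(fields) != 3:
            raise CloudFormatError(
                f"{path}: line {line_no}: expected 3 fields, got {len(fields)}"
            )
        try:
            rows.append([float(f) for f in fields])
        except ValueError as exc:
            raise CloudFormatError(f"{path}: line {line_no}: non-numeric value") from exc
        if n_expected is not None and len(rows) > n_expected:
            raise CloudFormatError(
                f"{path}: line {line_no}: more vertex rows than declared ({n_expected})"
            )
    return np.asarray(rows, dtype=float).reshape(-1, 3)


def read_xyz(path) -> np.ndarray:
    """Read an ASCII XYZ file into an (N, 3) array; empty file -> (0, 3)."""
    path = Path(path)
    with open(path) as fh:
        return _parse_rows(fh, path=str(path))


def write_xyz(coords: np.ndarray, path) -> None:
    coords = np.asarray(coords, dtype=float)
    if coords.size and not np.all(np.isfinite(coords)):
        raise ValueError("coords must be finite")
    with open(path, "w") as fh:
        for x, y, z in coords.reshape(-1, 3):
            fh.write(f"{x:.7f} {y:.7f} {z:.7f}\n")


def write_ply(cloud: LabeledCloud | np.ndarray, path) -> None:
    """Write an ASCII PLY; label/subject are stored as header comments."""
    if not isinstance(cloud, LabeledCloud):
        cloud = LabeledCloud(coords=np.asarray(cloud))
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        if cloud.label is not None:
            fh.write(f"comment class_id {int(cloud.label)}\n")
        if cloud.subject_id is not None:
            fh.write(f"comment subject_id {int(cloud.subject_id)}\n")
        fh.write(f"element vertex {cloud.n_points}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("end_header\n")
        for x, y, z in cloud.coords:
            fh.write(f"{x:.7f} {y:.7f} {z:.7f}\n")


def read_ply(path) -> LabeledCloud:
    """Read an ASCII PLY written by :func:`write_ply` (or compatible)."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise CloudFormatError(f"{path}: line 1: missing 'ply' magic")
    n_vertex = None
    label = None
    subject = None
    header_end = None
    saw_format = False
    for i, line in enumerate(lines[1:], start=2):
        fields = line.strip().split()
        if not fields:
            continue
        if fields[0] == "format":
            if fields[1:2] != ["ascii"]:
                raise CloudFormatError(
                    f"{path}: line {i}: only 'format ascii 1.0' is supported"
                )
            saw_format = True
        elif fields[0] == "comment" and len(fields) == 3:
            if fields[1] == "class_id":
                label = int(fields[2])
            elif fields[1] == "subject_id":
                subject = int(fields[2])
        elif fields[0] == "element":
            if fields[1] != "vertex":
                raise CloudFormatError(f"{path}: line {i}: unsupported element '{fields[1]}'")
            n_vertex = int(fields[2])
        elif fields[0] == "end_header":
            header_end = i
            break
    if not saw_format:
        raise CloudFormatError(f"{path}: missing 'format' line in header")
    if n_vertex is None or header_end is None:
        raise CloudFormatError(f"{path}: incomplete PLY header")
    coords = _parse_rows(lines[header_end:], n_expected=n_vertex, path=str(path),
                         first_line_no=header_end + 1)
    if coords.shape[0] != n_vertex:
        raise CloudFormatError(
            f"{path}: header declares {n_vertex} vertices but body has {coords.shape[0]}"
        )
    return LabeledCloud(coords=coords, label=label, subject_id=subject)


def remove_outliers(coords: np.ndarray, k: int = 8, sd_mult: float = 2.0) -> np.ndarray:
    """Indices of points kept by the statistical outlier filter.

    Point i is retained iff its mean distance to its k nearest neighbors is
    at most ``mean + sd_mult * sd`` of that statistic over the whole cloud.
    The returned index array is ascending (order-preserving).
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of points ({n})")
    tree = cKDTree(coords)
    dists, _ = tree.query(coords, k=k + 1)
    mean_knn = dists[:, 1:].mean(axis=1)
    thresh = mean_knn.mean() + sd_mult * mean_knn.std()
    return np.flatnonzero(mean_knn <= thresh)


def normalize_cloud(coords: np.ndarray) -> np.ndarray:
    """Center the cloud at the origin and scale its max norm to 1.

    A degenerate cloud (all points coincident) maps to all zeros.
    Idempotent; preserves shape up to the uniform scale.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
        raise ValueError("coords must be a nonempty (N, 3) array")
    centered = coords - coords.mean(axis=0)
    scale = np.linalg.norm(centered, axis=1).max()
    if scale < 1e-12:
        return np.zeros_like(centered)
    return centered / scale


@dataclass
class DatasetSplit:
    """Disjoint train/test partition of a labeled cloud dataset."""

    train: list
    test: list
    split_fraction: float
    seed: int
    train_indices: np.ndarray | None = None
    test_indices: np.ndarray | None = None


def split_dataset(dataset, fraction: float = 0.75, seed: int = 0,
                  stratify_by_class: bool = True) -> DatasetSplit:
    """Reproducible train/test split, stratified per gesture class by default.

    Under stratification a class with fewer than 2 clouds cannot be split;
    it is kept entirely in train with a warning.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    dataset = list(dataset)
    rng = np.random.default_rng(seed)
    n = len(dataset)
    train_idx: list[int] = []
    test_idx: list[int] = []
    if stratify_by_class:
        labels = np.array([c.label for c in dataset])
        for cls in np.unique(labels):
            members = np.flatnonzero(labels == cls)
            if members.size < 2:
                warnings.warn(
                    f"class {cls} has fewer than 2 clouds; keeping it all in train"
                )
                train_idx.extend(members.tolist())
                continue
            perm = rng.permutation(members)
            n_tr = int(round(fraction * members.size))
            n_tr = min(max(n_tr, 1), members.size - 1)
            train_idx.extend(perm[:n_tr].tolist())
            test_idx.extend(perm[n_tr:].tolist())
    else:
        perm = rng.permutation(n)
        n_tr = min(max(int(round(fraction * n)), 1), n - 1)
        train_idx = perm[:n_tr].tolist()
        test_idx = perm[n_tr:].tolist()
    train_idx = np.sort(np.asarray(train_idx, dtype=int))
    test_idx = np.sort(np.asarray(test_idx, dtype=int))
    return DatasetSplit(
        train=[dataset[i] for i in train_idx],
        test=[dataset[i] for i in test_idx],
        split_fraction=fraction,
        seed=seed,
        train_indices=train_idx,
        test_indices=test_idx,
    )


def write_manifest(entries, path) -> None:
    """Write a manifest CSV with columns filename, class_id, subject_id."""
    pd.DataFrame(entries, columns=["filename", "class_id", "subject_id"]).to_csv(
        path, index=False
    )


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"filename", "class_id", "subject_id"} - set(df.columns)
    if missing:
        raise CloudFormatError(f"{path}: manifest missing columns {sorted(missing)}")
    return df
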