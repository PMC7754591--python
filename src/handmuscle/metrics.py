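"""Segmentation accuracy metrics and reanalysis precision statistics.

Accuracy between a candidate mask R and a reference M:

* Dice ratio        D = 2|R ∩ M| / (|R| + |M|)
* average surface distance  d_avg = (1/|A|) Σ_{a∈A} min_{b∈B} d(a, b)
* Hausdorff distance        h = max_{a∈A} min_{b∈B} d(a, b)

d is the Euclidean metric in physical (mm) coordinates; A and B are the
mask surfaces (mask voxels with at least one face-adjacent background
neighbor, the image border counting as background), distances taken
between voxel centers. h as defined above is directed; a symmetric
variant is provided as well.

Precision over repeated analyses of the same subjects: RMS_SD is the root
mean square of the per-subject sample standard deviations, CV the root
mean square of per-subject (SD/mean)·100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .volume import BinaryMask

__all__ = [
    "AccuracyResult",
    "PrecisionResult",
    "dice",
    "surface_points",
    "average_surface_distance",
    "hausdorff",
    "symmetric_hausdorff",
    "precision_stats",
    "evaluate_pairs",
]

_FACE = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass(frozen=True)
class AccuracyResult:
    dice: float
    avg_surface_distance: float  # mm
    hausdorff: float  # mm


@dataclass(frozen=True)
class PrecisionResult:
    rms_sd: float  # measurement units
    cv: float  # %
    n_subjects: int
    n_repeats: int
    undefined_cv_subjects: tuple[int, ...] = ()


def _check_pair(a: BinaryMask, b: BinaryMask) -> None:
    if not a.same_geometry(b):
        raise ValueError("masks must share shape, spacing and origin")


def dice(r: BinaryMask, m: BinaryMask) -> float:
    """Dice overlap ratio; two empty masks count as perfect agreement."""
    _check_pair(r, m)
    nr, nm = r.voxel_count, m.voxel_count
    if nr + nm == 0:
        return 1.0
    inter = int(np.count_nonzero(r.data & m.data))
    return 2.0 * inter / (nr + nm)


def surface_points(mask: BinaryMask) -> np.ndarray:
    """Physical (mm) coordinates of the mask surface voxel centers.

    Surface voxels have at least one face-adjacent (6-connected) neighbor
    outside the mask; voxels on the image border are surface voxels.
    """
    interior = ndimage.binary_erosion(mask.data, structure=_FACE, border_value=0)
    surf = mask.data & ~interior
    zyx = np.argwhere(surf).astype(np.float64)
    sx, sy, sz = mask.spacing
    return zyx[:, ::-1] * np.array([sx, sy, sz]) + np.asarray(mask.origin)


def _directed_distances(a: BinaryMask, b: BinaryMask) -> np.ndarray:
    _check_pair(a, b)
    pa, pb = surface_points(a), surface_points(b)
    if pa.size == 0 or pb.size == 0:
        raise ValueError("surface distances require two nonempty masks")
    d, _ = cKDTree(pb).query(pa)
    return d


def average_surface_distance(a: BinaryMask, b: BinaryMask) -> float:
    """Mean distance from each surface point of A to the nearest of B (mm)."""
    return float(_directed_distances(a, b).mean())


def hausdorff(a: BinaryMask, b: BinaryMask) -> float:
    """Directed Hausdorff distance from A's surface to B's surface (mm)."""
    return float(_directed_distances(a, b).max())


def symmetric_hausdorff(a: BinaryMask, b: BinaryMask) -> float:
    """max(h(A→B), h(B→A)); never smaller than either directed value."""
    return max(hausdorff(a, b), hausdorff(b, a))


def precision_stats(measurements) -> PrecisionResult:
    """Reanalysis precision from per-subject repeated measurements.

    ``measurements`` maps subject id → sequence of repeated values (or is a
    list of sequences). Each subject needs ≥ 2 repeats. Per-subject SD is
    the sample SD (n−1). Subjects with zero mean have an undefined CV; they
    are excluded from the CV average and reported in the result.
    """
    if isinstance(measurements, dict):
        items = list(measurements.items())
    else:
        items = list(enumerate(measurements))
    if not items:
        raise ValueError("precision needs at least one subject")
    sds, cvs, undefined = [], [], []
    n_rep = None
    for subject, values in items:
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise ValueError(f"subject {subject!r} has fewer than 2 repeats")
        n_rep = v.size if n_rep is None else n_rep
        sd = float(v.std(ddof=1))
        sds.append(sd)
        mean = float(v.mean())
        if mean == 0:
            undefined.append(subject)
        else:
            cvs.append(sd / mean * 100.0)
    rms_sd = float(np.sqrt(np.mean(np.square(sds))))
    cv = float(np.sqrt(np.mean(np.square(cvs)))) if cvs else float("nan")
    return PrecisionResult(
        rms_sd=rms_sd,
        cv=cv,
        n_subjects=len(items),
        n_repeats=n_rep or 0,
        undefined_cv_subjects=tuple(undefined),
    )


def evaluate_pairs(pairs) -> pd.DataFrame:
    """Accuracy metrics for (automatic, reference) mask pairs.

    Returns a DataFrame with one row per pair (columns ``dice``, ``d_avg``,
    ``hausdorff``) followed by ``mean``/``sd``/``min``/``max`` summary rows.
    Distance metrics use the directed convention, automatic → reference.
    """
    rows = []
    for i, (auto, ref) in enumerate(pairs):
        rows.append(
            {
                "case": str(i),
                "dice": dice(auto, ref),
                "d_avg": average_surface_distance(auto, ref),
                "hausdorff": hausdorff(auto, ref),
            }
        )
    if not rows:
        raise ValueError("no mask pairs to evaluate")
    df = pd.DataFrame(rows)
    metrics = df[["dice", "d_avg", "hausdorff"]]
    summary = pd.DataFrame(
        {
            "case": ["mean", "sd", "min", "max"],
            "dice": [metrics["dice"].mean(), metrics["dice"].std(ddof=1), metrics["dice"].min(), metrics["dice"].max()],
            "d_avg": [metrics["d_avg"].mean(), metrics["d_avg"].std(ddof=1), metrics["d_avg"].min(), metrics["d_avg"].max()],
            "hausdorff": [metrics["hausdorff"].mean(), metrics["hausdorff"].std(ddof=1), metrics["hausdorff"].min(), metrics["hausdorff"].max()],
        }
    )
    if len(rows) == 1:
        summary.loc[summary["case"] == "sd", ["dice", "d_avg", "hausdorff"]] = 0.0
    return pd.concat([df, summary], ignore_index=True)
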