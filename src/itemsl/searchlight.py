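"""Searchlight construction and map-wise decoding.

A searchlight is the set of in-mask voxels whose centers lie within a given
Euclidean radius (in mm) of a center voxel; decoding within the searchlight
of every in-mask voxel yields a whole-volume map of decoding performance
(accuracy for classification, predictive correlation for regression).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import nibabel as nib
import numpy as np

from .decoding import (
    balanced_accuracy,
    classify,
    crossvalidate,
    decoding_accuracy,
    median_absolute_error,
    predictive_correlation,
)
from .design import TransformationMatrix
from .estimators import TrialEstimates

__all__ = [
    "SearchlightIndex",
    "PerformanceMap",
    "build_searchlight_index",
    "run_searchlight",
    "read_volume",
    "write_volume",
    "performance_map_to_image",
]


@dataclass
class SearchlightIndex:
    """Per-center lists of in-mask voxel indices within a spherical radius.

    ``in_mask_coords`` enumerates in-mask voxels (the column order of any
    paired estimate matrix); ``neighbors[i]`` indexes that enumeration.
    """

    in_mask_coords: np.ndarray  # m x 3 voxel indices
    neighbors: list[np.ndarray]
    radius: float
    voxel_size: np.ndarray
    mask: np.ndarray

    @property
    def n_centers(self) -> int:
        return len(self.neighbors)

    def sizes(self) -> np.ndarray:
        return np.array([n.size for n in self.neighbors])


def build_searchlight_index(
    mask: np.ndarray, radius: float, voxel_size: float | tuple[float, float, float] = 1.0
) -> SearchlightIndex:
    """Spherical searchlights around every in-mask voxel.

    Distances are Euclidean in mm between voxel centers with inclusive
    boundary (``<= radius``); anisotropic voxels are supported via per-axis
    sizes.  Boundary voxels keep truncated spheres.

    Parameters
    ----------
    mask : 3-D boolean array
    radius : float, mm (>= 0)
    voxel_size : float or 3-tuple, mm per axis
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3-D")
    if not mask.any():
        raise ValueError("mask is empty")
    if radius < 0:
        raise ValueError("radius must be non-negative")
    vs = np.broadcast_to(np.atleast_1d(np.asarray(voxel_size, float)), (3,)).copy()
    if (vs <= 0).any():
        raise ValueError("voxel sizes must be positive")

    coords = np.argwhere(mask)
    index_vol = -np.ones(mask.shape, dtype=int)
    index_vol[tuple(coords.T)] = np.arange(len(coords))

    # integer offsets whose mm-distance is within the radius
    max_off = np.floor(radius / vs).astype(int)
    offsets = [
        np.array(o)
        for o in product(*(range(-m, m + 1) for m in max_off))
        if np.sum((np.array(o) * vs) ** 2) <= radius**2 + 1e-9
    ]
    offsets = np.array(offsets)

    shape = np.array(mask.shape)
    neighbors = []
    for c in coords:
        pts = c + offsets
        ok = np.all((pts >= 0) & (pts < shape), axis=1)
        idx = index_vol[tuple(pts[ok].T)]
        neighbors.append(np.sort(idx[idx >= 0]))
    return SearchlightIndex(coords, neighbors, float(radius), vs, mask)


@dataclass
class PerformanceMap:
    """Voxel-wise decoding-performance values (NaN outside the mask)."""

    values: np.ndarray
    metric: str
    target: str

    def __post_init__(self) -> None:
        m = self.metric.upper()
        finite = self.values[np.isfinite(self.values)]
        if m in ("DA", "BA") and finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("accuracy map values must lie in [0, 1]")
        if m == "CC" and finite.size and (finite.min() < -1 or finite.max() > 1):
            raise ValueError("correlation map values must lie in [-1, 1]")

    def peak_voxel(self) -> tuple[int, ...]:
        return tuple(np.unravel_index(np.nanargmax(self.values), self.values.shape))


def _score(pred, T: TransformationMatrix, task: str, metric: str, target_cols):
    out = {}
    if task == "classification":
        idx = T.indicator_columns
        lab = classify(pred.predicted[:, idx])
        tru = classify(pred.actual[:, idx])
        fn = decoding_accuracy if metric.upper() == "DA" else balanced_accuracy
        for j in target_cols:  # one map per contrast; same pooled value per column set
            out[T.column_names[j] if j is not None else "all"] = fn(lab, tru)
    else:
        for j in target_cols:
            p, a = pred.predicted[:, j], pred.actual[:, j]
            if metric.upper() == "MAE":
                out[T.column_names[j]] = median_absolute_error(p, a)
            else:
                out[T.column_names[j]] = predictive_correlation(p, a)
    return out


def run_searchlight(
    estimates: TrialEstimates,
    index: SearchlightIndex,
    T: TransformationMatrix,
    task: str = "classification",
    method: str = "ITEM",
    metric: str | None = None,
    targets: list[str] | None = None,
    use_reml: bool = True,
    min_voxels: int = 1,
    allow_pinv: bool = False,
    labels: list[np.ndarray] | None = None,
) -> dict[str, PerformanceMap]:
    """Decode within every searchlight and assemble performance maps.

    Parameters
    ----------
    estimates : TrialEstimates
        Columns ordered like ``index.in_mask_coords``.
    T : TransformationMatrix
        Design variables per trial (rows aligned with the estimates).
    task : "classification" or "regression"
    method : "ITEM" (analytic inversion) or "baseline" (linear SVC on the
        raw estimates; classification only).
    metric : DA | BA for classification (default DA), CC | MAE for
        regression (default CC).
    targets : regression column names (default: all parametric columns).

    Returns
    -------
    dict mapping target name -> PerformanceMap.  Centers with fewer than
    ``min_voxels`` neighbors get NaN.
    """
    if estimates.n_voxels != index.n_centers:
        raise ValueError(
            f"estimates have {estimates.n_voxels} voxels but the index has "
            f"{index.n_centers} in-mask voxels"
        )
    task = task.lower()
    if task not in ("classification", "regression"):
        raise ValueError("task must be 'classification' or 'regression'")
    if metric is None:
        metric = "DA" if task == "classification" else "CC"
    if task == "classification":
        target_cols: list = [None]
    else:
        names = T.column_names
        wanted = targets or [
            n for n, k in zip(names, T.column_kind) if k == "parametric"
        ]
        target_cols = [names.index(n) for n in wanted]

    first_names = (
        ["all"] if task == "classification" else [T.column_names[j] for j in target_cols]
    )
    maps = {
        name: np.full(index.mask.shape, np.nan) for name in first_names
    }
    for ci in range(index.n_centers):
        cols = index.neighbors[ci]
        if cols.size < min_voxels:
            continue
        sub = estimates.subset_voxels(cols)
        if method.upper() == "ITEM":
            pred = crossvalidate(sub, T, use_reml=use_reml, allow_pinv=allow_pinv)
            scores = _score(pred, T, task, metric, target_cols)
        elif method.lower() == "baseline":
            if task != "classification":
                raise ValueError("baseline searchlight supports classification only")
            if labels is None:
                idx = T.indicator_columns
                lab_all = classify(T.matrix[:, idx])
                labels_ = [
                    lab_all[sub.session_rows(s)] for s in sub.sessions
                ]
            else:
                labels_ = labels
            from .simulation import _svc_accuracy

            scores = {"all": _svc_accuracy(sub, labels_)}
        else:
            raise ValueError(f"unknown searchlight method {method!r}")
        loc = tuple(index.in_mask_coords[ci])
        for name, val in scores.items():
            maps[name][loc] = val
    return {
        name: PerformanceMap(vals, metric, name) for name, vals in maps.items()
    }


# ---------------------------------------------------------------------------
# NIfTI plumbing
# ---------------------------------------------------------------------------

def write_volume(path, data: np.ndarray, affine: np.ndarray | None = None) -> None:
    """Write a 3-D/4-D array as NIfTI-1 (identity affine by default)."""
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


def read_volume(path, match_affine: np.ndarray | None = None):
    """Read a NIfTI volume; optionally enforce a matching affine.

    Returns ``(data, affine)``.  Raises when ``match_affine`` is given and
    the stored affine differs (paired mask/data grids must be congruent).
    """
    img = nib.load(str(path))
    affine = img.affine
    if match_affine is not None and not np.allclose(affine, match_affine, atol=1e-4):
        raise ValueError("affine mismatch between paired volumes")
    return np.asarray(img.get_fdata()), affine


def performance_map_to_image(pmap: PerformanceMap, affine: np.ndarray | None = None):
    """Wrap a performance map as a NIfTI image (NaN outside the mask)."""
    if affine is None:
        affine = np.eye(4)
    return nib.Nifti1Image(pmap.values.astype(np.float64), affine)
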