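"""Compartment segmentation: anatomic masks and activity-isocontour thresholding.

Two routes to the tumor/normal compartments are supported.  The *anatomic*
route takes binary masks as given (standing in for contours drawn on
diagnostic CT/MRI).  The *maa_threshold* route segments directly on the
count map: inside a user-defined box, every voxel whose counts reach a chosen
fraction of the in-box maximum joins the mask, optionally clipped to the
liver or perfused volume.

Either way, the compartment algebra is the same:

* perfused normal liver  = perfused liver minus all tumors >= 2 cm,
* total perfused tumor   = union of tumors >= 3 cm, inside the perfused volume,
* whole-liver normal     = whole liver minus all tumors >= 2 cm.

Tumors of 2–3 cm are therefore counted in neither normal tissue nor the
total-perfused-tumor compartment; tumors under 2 cm stay part of normal
tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .grids import VoxelGrid
from .phantom import Lesion

__all__ = [
    "ThresholdSpec",
    "CompartmentSet",
    "threshold_segment",
    "lesion_diameter",
    "derive_compartments",
    "TUMOR_NORMAL_EXCLUSION_CM",
    "TOTAL_PERFUSED_TUMOR_CM",
]

# Size rules for the compartment algebra (cm, longest axis).
TUMOR_NORMAL_EXCLUSION_CM = 2.0   # tumors >= this leave the normal compartments
TOTAL_PERFUSED_TUMOR_CM = 3.0     # tumors >= this form total perfused tumor


@dataclass
class ThresholdSpec:
    """Isocontour threshold inside a voxel-index box.

    The box is 0-based and half-open: ``box = ((x0, x1), (y0, y1), (z0, z1))``
    selects voxels with x0 <= x < x1 etc.  ``fraction`` is the threshold t in
    [0, 1] relative to the in-box maximum; comparison is inclusive (>=), so
    ties at the threshold value are kept.  ``clip`` restricts the result to a
    mask (typically the liver or perfused volume).
    """

    box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    fraction: float = 0.30
    clip: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("fraction must lie in [0, 1]")
        for lo, hi in self.box:
            if hi <= lo:
                raise ValueError("box must be non-empty on every axis")


@dataclass
class CompartmentSet:
    """The five study compartments plus per-lesion masks, tagged by method."""

    whole_liver: np.ndarray
    perfused: np.ndarray
    tumors: list[Lesion]
    perfused_normal: np.ndarray
    total_perfused_tumor: np.ndarray
    whole_liver_normal: np.ndarray
    method: str = "anatomic"

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "whole_liver": self.whole_liver,
            "perfused": self.perfused,
            "perfused_normal": self.perfused_normal,
            "total_perfused_tumor": self.total_perfused_tumor,
            "whole_liver_normal": self.whole_liver_normal,
        }


def threshold_segment(counts: VoxelGrid, spec: ThresholdSpec) -> np.ndarray:
    """Activity-isocontour segmentation within a box.

    Returns the boolean mask of in-box voxels whose counts are >= fraction of
    the in-box maximum, intersected with the clip mask if one is given.
    """
    shape = counts.shape
    for (lo, hi), n in zip(spec.box, shape):
        if lo < 0 or hi > n:
            raise ValueError(f"box [{lo}, {hi}) outside grid axis of length {n}")
    sl = tuple(slice(lo, hi) for lo, hi in spec.box)
    box_vals = counts.values[sl]
    vmax = box_vals.max()
    if vmax == 0 and spec.fraction > 0:
        warnings.warn("all-zero box with positive threshold: empty mask", stacklevel=2)
        return np.zeros(shape, dtype=bool)
    mask = np.zeros(shape, dtype=bool)
    mask[sl] = box_vals >= spec.fraction * vmax
    if spec.clip is not None:
        mask &= np.asarray(spec.clip, dtype=bool)
    return mask


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 26-connected component (optional post-filter)."""
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    if n <= 1:
        return mask.copy()
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def lesion_diameter(mask: np.ndarray, spacing_mm: float) -> float:
    """Longest axis of a mask in cm: max pairwise distance of voxel centers.

    For large masks the candidate points are reduced to the convex hull
    vertices first; the answer is identical because the diameter of a finite
    point set is attained on its hull.
    """
    pts = np.argwhere(mask).astype(float)
    if pts.shape[0] == 0:
        raise ValueError("empty mask has no diameter")
    if pts.shape[0] == 1:
        return 0.0
    if pts.shape[0] > 500:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate (coplanar/collinear) masks: brute force below
    return float(pdist(pts).max() * spacing_mm / 10.0)


def _tumor_union(
    tumors: list[Lesion], min_diameter_cm: float, shape: tuple[int, int, int]
) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    for t in tumors:
        if t.diameter_cm >= min_diameter_cm:
            out |= t.mask
    return out


def derive_compartments(
    whole_liver: np.ndarray,
    perfused: np.ndarray,
    tumors: list[Lesion],
    method: str = "anatomic",
) -> CompartmentSet:
    """Apply the compartment-definition algebra to liver/perfused/tumor masks."""
    whole_liver = np.asarray(whole_liver, dtype=bool)
    perfused = np.asarray(perfused, dtype=bool)
    if whole_liver.shape != perfused.shape:
        raise ValueError("whole_liver and perfused masks must share a shape")
    if (perfused & ~whole_liver).any():
        raise ValueError("perfused volume must lie inside the whole liver")
    for t in tumors:
        if t.mask.shape != whole_liver.shape:
            raise ValueError(f"tumor {t.id!r} mask shape mismatch")

    ge2 = _tumor_union(tumors, TUMOR_NORMAL_EXCLUSION_CM, whole_liver.shape)
    ge3 = _tumor_union(tumors, TOTAL_PERFUSED_TUMOR_CM, whole_liver.shape)
    return CompartmentSet(
        whole_liver=whole_liver,
        perfused=perfused,
        tumors=list(tumors),
        perfused_normal=perfused & ~ge2,
        total_perfused_tumor=ge3 & perfused,
        whole_liver_normal=whole_liver & ~ge2,
        method=method,
    )
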