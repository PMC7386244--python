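"""Visualization encodings: HSV multi-feature spot colors, nuclei point
patterns, and the 3D section stack.

The HSV multi-feature view shows several non-overlapping factors (or genes)
at once: feature i of k gets the hue i/k (even breaks around the color
wheel), every feature is min-max rescaled to [0, 1] across all spots, and
each spot takes the hue of its highest-valued feature with that rescaled
value as brightness — a spot where everything is zero stays black.

For 3D models, a deliberately simple nuclei segmentation (in-tissue Otsu
threshold on luminance, connected components, centroids) produces a 2D point
pattern per aligned section; stacking assigns section i the plane
``z = i * z_spacing``, where the spacing can be expanded or contracted for
display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from matplotlib.colors import hsv_to_rgb
from scipy import ndimage

from .datamodel import SectionImage, TissueMask
from .masking import DegenerateImageError, otsu_threshold

__all__ = [
    "hsv_multifeature",
    "segment_nuclei",
    "stack_sections",
    "NucleiPointCloud",
    "write_point_cloud_csv",
    "write_point_cloud_ply",
]


@dataclass
class NucleiPointCloud:
    """Nuclei centroids across a section stack: M x 3 (x, y, z) points."""

    points: np.ndarray
    section_index: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.section_index = np.asarray(self.section_index, dtype=int)
        if len(self.section_index) != len(self.points):
            raise ValueError("section_index must match point count")


def hsv_multifeature(F: np.ndarray, per_feature_range=None) -> np.ndarray:
    """Encode a k x n feature matrix as n RGB spot colors.

    Feature i gets hue ``i / k``; features are min-max rescaled to [0, 1]
    across spots (a constant feature rescales to all zeros rather than
    erroring); each spot is colored ``HSV(hue_winner, 1, winner value)``
    where the winner is the argmax of the rescaled values, ties going to the
    lowest feature index. All-zero spots come out black. Positive rescaling
    of any single feature leaves every color unchanged.

    ``per_feature_range`` optionally supplies (min, max) pairs — e.g. from a
    jointly-scaled multi-section run — instead of the observed range.
    """
    F = np.asarray(F, dtype=float)
    if F.ndim != 2 or F.shape[0] < 1:
        raise ValueError("F must be k x n with k >= 1")
    if not np.isfinite(F).all():
        raise ValueError("feature values must be finite")
    k, n = F.shape
    if per_feature_range is None:
        lo = F.min(axis=1)
        hi = F.max(axis=1)
    else:
        lo = np.asarray([r[0] for r in per_feature_range], dtype=float)
        hi = np.asarray([r[1] for r in per_feature_range], dtype=float)
    span = hi - lo
    scaled = np.zeros_like(F)
    ok = span > 0
    scaled[ok] = (F[ok] - lo[ok, None]) / span[ok, None]
    scaled = np.clip(scaled, 0.0, 1.0)

    winner = np.argmax(scaled, axis=0)  # ties -> lowest index (argmax semantics)
    value = scaled[winner, np.arange(n)]
    hue = winner / k
    hsv = np.column_stack([hue, np.ones(n), value])
    rgb = hsv_to_rgb(hsv)
    rgb[value == 0] = 0.0
    return rgb


def segment_nuclei(img: SectionImage, mask: TissueMask, min_area_px: int = 2,
                   min_contrast: float = 0.15, seed: int = 0) -> np.ndarray:
    """Nuclei centroids inside the tissue mask, as M x 2 (x, y) pixels.

    Luminance is thresholded by Otsu *restricted to in-mask pixels*; pixels
    darker than the threshold form candidate nuclei, whose connected
    components of at least ``min_area_px`` pixels are reported by centroid.
    If the two Otsu classes differ by less than ``min_contrast`` in mean
    luminance, the tissue is considered featureless (no stained nuclei, only
    texture) and no points are returned. Touching nuclei are not declumped —
    this trades precision for speed and is sufficient to capture overall
    tissue morphology.
    """
    if img.shape != mask.shape:
        raise ValueError(f"image {img.shape} and mask {mask.shape} frames differ")
    if not mask.pixels.any():
        return np.empty((0, 2))
    gray = img.grayscale()
    inside = gray[mask.pixels]
    try:
        thr = otsu_threshold(inside)
    except DegenerateImageError:
        return np.empty((0, 2))  # featureless tissue: nothing darker to segment
    lo = inside[inside <= thr]
    hi = inside[inside > thr]
    if not len(lo) or not len(hi) or hi.mean() - lo.mean() < min_contrast:
        return np.empty((0, 2))
    dark = (gray < thr) & mask.pixels
    labels, n = ndimage.label(dark)
    if n == 0:
        return np.empty((0, 2))
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(areas >= min_area_px) + 1
    if len(keep) == 0:
        return np.empty((0, 2))
    centroids = ndimage.center_of_mass(dark, labels, keep)  # (row, col)
    return np.array([(c, r) for r, c in centroids], dtype=float)


def stack_sections(point_sets, z_spacing: float) -> NucleiPointCloud:
    """Assemble per-section 2D point patterns into one 3D cloud.

    Section i's points get ``z = i * z_spacing``; changing ``z_spacing``
    contracts or expands the stack linearly. Point counts are conserved and
    each section stays planar.
    """
    if not z_spacing > 0:
        raise ValueError("z_spacing must be positive")
    pts = []
    idx = []
    for i, ps in enumerate(point_sets):
        ps = np.asarray(ps, dtype=float).reshape(-1, 2)
        z = np.full(len(ps), i * z_spacing)
        pts.append(np.column_stack([ps, z]))
        idx.append(np.full(len(ps), i, dtype=int))
    points = np.vstack(pts) if pts else np.empty((0, 3))
    section_index = np.concatenate(idx) if idx else np.empty(0, dtype=int)
    return NucleiPointCloud(points=points, section_index=section_index)


def write_point_cloud_csv(cloud: NucleiPointCloud, path) -> None:
    pd.DataFrame({
        "x": cloud.points[:, 0], "y": cloud.points[:, 1], "z": cloud.points[:, 2],
        "section": cloud.section_index,
    }).to_csv(path, index=False)


def write_point_cloud_ply(cloud: NucleiPointCloud, path) -> None:
    """ASCII PLY export of the nuclei point cloud."""
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(cloud.points)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("end_header\n")
        for x, y, z in cloud.points:
            fh.write(f"{x:.3f} {y:.3f} {z:.3f}\n")
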