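"""Rigid serial-section alignment by iterative closest point (ICP).

Sections are aligned to a chosen reference using only their tissue-mask
boundaries: edge pixels are extracted from each binary mask, and ICP
alternates nearest-neighbor correspondence with a least-squares rigid fit
(Kabsch/SVD) until the correspondence RMSD stops improving. Reflections —
sections mounted flipped — are handled by running a second branch on the
mirrored source and keeping whichever branch ends with the lower RMSD.
The recovered transform is applied to images by backward warping with
bicubic interpolation and to spot coordinates by plain matrix action.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.transform import AffineTransform, warp

from .datamodel import RigidTransform, TissueMask

__all__ = [
    "EdgePointSet",
    "extract_edge_points",
    "icp_register",
    "apply_rigid",
    "warp_image_backward",
    "align_stack",
    "map_spot_coordinates",
]


@dataclass
class EdgePointSet:
    """Tissue-boundary pixel coordinates (x, y) in the working-image frame."""

    section_id: str
    points: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be N x 2")
        if len(self.points) < 3:
            raise ValueError("need at least 3 edge points")


def extract_edge_points(mask: TissueMask, max_points: int = 2000, seed: int = 0) -> EdgePointSet:
    """Boundary pixels of a tissue mask (mask minus its erosion).

    On a binary raster this is exactly the set of pixels with nonzero
    gradient magnitude. If more than ``max_points`` boundary pixels exist, a
    seeded uniform subsample of ``max_points`` is returned.
    """
    m = mask.pixels
    if not m.any() or m.all():
        raise ValueError("mask must contain both tissue and background")
    eroded = ndimage.binary_erosion(m, structure=np.ones((3, 3)), border_value=0)
    boundary = m & ~eroded
    ys, xs = np.nonzero(boundary)
    points = np.column_stack([xs, ys]).astype(float)
    if len(points) > max_points:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(points), size=max_points, replace=False)
        idx.sort()
        points = points[idx]
    return EdgePointSet(section_id=mask.section_id, points=points)


def _kabsch(src: np.ndarray, dst: np.ndarray) -> tuple:
    """Least-squares proper rotation + translation mapping src onto dst."""
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    H = (src - mu_s).T @ (dst - mu_d)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, d]) @ U.T
    t = mu_d - R @ mu_s
    return R, t


def _rotation(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s], [s, c]])


def _icp_branch(src: np.ndarray, tree: cKDTree, target: np.ndarray,
                max_iter: int, tol: float, init=None,
                trim_fraction: float = 0.0) -> tuple:
    """ICP restricted to proper rotations. Returns (R, t, trace, converged, rmsd).

    With ``trim_fraction`` > 0 the worst correspondences are excluded from
    both the objective and the rigid refit (robustness to partial overlap).
    """
    if init is None:
        R, t = np.eye(2), np.zeros(2)
    else:
        R, t = init
    n_keep = max(3, int(np.ceil(len(src) * (1.0 - trim_fraction))))
    trace = []
    converged = False
    prev = np.inf
    best = (R, t, np.inf)
    for _ in range(max_iter):
        moved = src @ R.T + t
        dist, idx = tree.query(moved)
        if n_keep < len(src):
            keep = np.argsort(dist, kind="stable")[:n_keep]
        else:
            keep = slice(None)
        rmsd = float(np.sqrt(np.mean(dist[keep] ** 2)))
        trace.append(rmsd)
        if rmsd < best[2]:
            best = (R, t, rmsd)
        if prev - rmsd < tol * max(prev, 1e-12):
            converged = True
            break
        prev = rmsd
        R, t = _kabsch(src[keep], target[idx[keep]])
    return best[0], best[1], trace, converged, best[2]


def icp_register(
    source: EdgePointSet,
    target: EdgePointSet,
    allow_reflection: bool = True,
    max_iter: int = 100,
    tol: float = 1e-6,
    trim_fraction: float = 0.0,
    seed: int = 0,
) -> RigidTransform:
    """Rigid transform mapping ``source`` points into the ``target`` frame.

    Each iteration pairs every transformed source point with its nearest
    target point and refits the rotation/translation by SVD; iteration stops
    when the relative RMSD improvement drops below ``tol``. With
    ``allow_reflection`` a second branch is run on the x-mirrored source and
    the branch with the lower final RMSD wins. Non-convergence is not an
    error: the best iterate is returned with ``converged=False``.

    Because plain ICP only converges locally, each branch is restarted from
    a coarse sweep of initial rotations (30-degree steps, centroids
    pre-aligned) and the restart ending at the lowest RMSD is kept. The RMSD
    trace of the winning restart is attached as ``objective_trace`` and is
    non-increasing (for the default untrimmed objective).

    ``trim_fraction`` > 0 drops that fraction of worst correspondences each
    iteration, for sections with only partial overlap; default off.
    """
    src = source.points
    tgt = target.points
    tree = cKDTree(tgt)
    mu_t = tgt.mean(axis=0)

    def run_branch(pts):
        mu_s = pts.mean(axis=0)
        best = None
        for angle in np.arange(0.0, 360.0, 30.0):
            R0 = _rotation(np.deg2rad(angle))
            t0 = mu_t - R0 @ mu_s
            result = _icp_branch(pts, tree, tgt, max_iter, tol, init=(R0, t0),
                                 trim_fraction=trim_fraction)
            if best is None or result[4] < best[4]:
                best = result
        return best

    branches = []
    R, t, trace, conv, rmsd = run_branch(src)
    branches.append((R, t, trace, conv, rmsd, False))
    if allow_reflection:
        mirror = np.diag([-1.0, 1.0])
        Rm, tm, trm, convm, rmsdm = run_branch(src @ mirror)
        # Compose the mirror into the linear part: x -> Rm (M x) + tm.
        branches.append((Rm @ mirror, tm, trm, convm, rmsdm, True))

    R, t, trace, conv, rmsd, reflected = min(branches, key=lambda b: b[4])
    M = np.eye(3)
    M[:2, :2] = R
    M[:2, 2] = t
    out = RigidTransform(M, is_reflection=reflected, converged=conv, rmsd=rmsd)
    out.objective_trace = trace
    return out


def apply_rigid(points: np.ndarray, T: RigidTransform) -> np.ndarray:
    """Apply a rigid transform to N x 2 (x, y) coordinates."""
    pts = np.asarray(points, dtype=float)
    squeeze = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if not np.all(np.isfinite(pts)):
        raise ValueError("coordinates must be finite")
    out = pts @ T.matrix[:2, :2].T + T.matrix[:2, 2]
    return out[0] if squeeze else out


def warp_image_backward(img, T: RigidTransform, out_shape=None, fill=1.0,
                        order: int = 3):
    """Resample an image into the frame defined by transform ``T``.

    Backward warping: each output pixel samples the input at the inverse-
    transformed coordinate with bicubic interpolation (``order=3``); samples
    falling outside the input take the ``fill`` value (white by default,
    matching the stained-slide background).

    Accepts a :class:`SectionImage` (returned as one) or a bare array.
    """
    from .datamodel import SectionImage

    pixels = img.pixels if isinstance(img, SectionImage) else np.asarray(img, dtype=float)
    if out_shape is None:
        out_shape = pixels.shape[:2]
    tform = AffineTransform(matrix=T.matrix)
    warped = warp(
        pixels, inverse_map=tform.inverse, output_shape=out_shape,
        order=order, cval=fill, mode="constant", preserve_range=True,
    )
    warped = np.clip(warped, 0.0, 1.0) if pixels.dtype.kind == "f" else warped
    if isinstance(img, SectionImage):
        return SectionImage(img.section_id, warped, img.scale)
    return warped


def align_stack(masks, reference_index: int = 0, allow_reflection: bool = True,
                max_points: int = 2000, max_iter: int = 100, tol: float = 1e-6,
                seed: int = 0):
    """Register every tissue mask to the reference section's mask.

    Returns one :class:`RigidTransform` per input mask; the reference entry
    is the identity. Each transform maps that section's working-frame
    coordinates into the reference frame.
    """
    masks = list(masks)
    if not masks:
        raise ValueError("need at least one mask")
    if not 0 <= reference_index < len(masks):
        raise ValueError(f"reference_index {reference_index} out of range")
    edges = []
    for mask in masks:
        try:
            edges.append(extract_edge_points(mask, max_points=max_points, seed=seed))
        except ValueError as exc:
            raise ValueError(f"degenerate mask for section {mask.section_id!r}: {exc}") from exc
    ref = edges[reference_index]
    transforms = []
    for i, edge in enumerate(edges):
        if i == reference_index:
            transforms.append(RigidTransform.identity())
        else:
            transforms.append(icp_register(edge, ref, allow_reflection=allow_reflection,
                                           max_iter=max_iter, tol=tol, seed=seed))
    return transforms


def map_spot_coordinates(spots, T: RigidTransform, scale: float):
    """Carry full-resolution spot pixel coordinates through a working-frame
    transform.

    ``scale`` is the working-image scale (working px per full-resolution px)
    that the registration ran at: coordinates are scaled down into the
    working frame, transformed, and scaled back. Array coordinates are left
    untouched. Returns a copy of the spot table.
    """
    out = spots.copy()
    pts = np.column_stack([out["px_x"].to_numpy(float), out["px_y"].to_numpy(float)])
    moved = apply_rigid(pts * scale, T) / scale
    out["px_x"] = moved[:, 0]
    out["px_y"] = moved[:, 1]
    return out
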