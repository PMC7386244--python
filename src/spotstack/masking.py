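"""Tissue segmentation of stained section images.

The pipeline downscales the image to a 400-pixel working width, converts to
luminance, normalizes contrast around an Otsu threshold, blurs, clusters
pixels into compact superpixels (SLIC), and k-means-clusters the superpixel
mean colors into exactly two classes — inside and outside tissue. The tissue
class is the darker, more central one; small holes and specks (< 1% of the
frame) are cleaned up afterwards.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.transform import resize
from sklearn.cluster import KMeans

from .datamodel import SectionImage, TissueMask

__all__ = [
    "downscale_image",
    "otsu_threshold",
    "slic_superpixels",
    "compute_tissue_mask",
    "DegenerateImageError",
]


class DegenerateImageError(ValueError):
    """The image has no contrast to segment (e.g. constant color)."""


def downscale_image(img: SectionImage, target_width: int = 400) -> SectionImage:
    """Resize to ``target_width`` pixels wide, keeping the aspect ratio.

    Images already at or below the target width are returned unchanged. The
    image's ``scale`` (raster px per full-resolution px) is multiplied by the
    resize factor so spot coordinates keep mapping onto the raster.
    """
    if target_width < 16:
        raise ValueError(f"target_width must be >= 16, got {target_width}")
    h, w = img.shape
    if w <= target_width:
        return img
    factor = target_width / w
    new_h = max(1, round(h * factor))
    pixels = resize(img.pixels, (new_h, target_width), order=1, anti_aliasing=True)
    return SectionImage(img.section_id, np.clip(pixels, 0, 1), img.scale * factor)


def otsu_threshold(gray: np.ndarray) -> float:
    """Histogram threshold maximizing between-class variance (256 bins)."""
    gray = np.asarray(gray, dtype=float)
    if np.ptp(gray) == 0:
        raise DegenerateImageError("constant image: Otsu threshold undefined")
    return float(threshold_otsu(gray, nbins=256))


def slic_superpixels(img: SectionImage, n_segments: int, compactness: float = 10.0,
                     seed: int = 0, n_iter: int = 10) -> np.ndarray:
    """Compact superpixels by localized k-means in color + position space.

    Cluster centers start on a regular grid (at most ``n_segments`` of them)
    and each iteration assigns every pixel to the center, within a local
    search window, minimizing the combined distance

        d^2 = d_color^2 + (compactness / S)^2 * d_xy^2

    where S is the expected superpixel side length and colors are scaled to
    a 0-100 range so ``compactness`` has its conventional meaning. After
    convergence, stray disconnected fragments are reattached to the nearest
    main segment so every segment is spatially connected.

    Returns an H x W integer label raster with ids forming a contiguous
    range starting at 0. The procedure is deterministic (grid-seeded);
    ``seed`` is accepted for API uniformity. When ``n_segments`` equals the
    pixel count the unique minimizer assigns each pixel its own segment,
    which is returned directly.
    """
    h, w = img.shape
    if n_segments < 2:
        raise ValueError("n_segments must be >= 2")
    if n_segments > h * w:
        raise ValueError(f"n_segments={n_segments} exceeds pixel count {h * w}")
    if n_segments == h * w:
        return np.arange(h * w).reshape(h, w)

    color = img.pixels * 100.0  # Lab-like magnitude so compactness=10 is balanced
    S = np.sqrt(h * w / n_segments)
    rows = int(np.clip(round(np.sqrt(n_segments * h / w)), 1, n_segments))
    cols = max(1, n_segments // rows)
    cy = (np.arange(rows) + 0.5) * h / rows
    cx = (np.arange(cols) + 0.5) * w / cols
    centers_yx = np.array([(y, x) for y in cy for x in cx])
    k = len(centers_yx)
    iy = np.clip(centers_yx[:, 0].astype(int), 0, h - 1)
    ix = np.clip(centers_yx[:, 1].astype(int), 0, w - 1)
    centers_c = color[iy, ix]

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    wspace = (compactness / S) ** 2
    half_y = max(S, h / (2 * rows) + 1)
    half_x = max(S, w / (2 * cols) + 1)
    labels = np.zeros((h, w), dtype=int)
    for _ in range(n_iter):
        dist = np.full((h, w), np.inf)
        for c in range(k):
            y0 = max(0, int(centers_yx[c, 0] - half_y))
            y1 = min(h, int(centers_yx[c, 0] + half_y) + 1)
            x0 = max(0, int(centers_yx[c, 1] - half_x))
            x1 = min(w, int(centers_yx[c, 1] + half_x) + 1)
            win = (slice(y0, y1), slice(x0, x1))
            d = ((color[win] - centers_c[c]) ** 2).sum(axis=-1)
            d += wspace * ((yy[win] - centers_yx[c, 0]) ** 2
                           + (xx[win] - centers_yx[c, 1]) ** 2)
            closer = d < dist[win]
            dist[win][closer] = d[closer]
            labels[win][closer] = c
        for c in range(k):
            sel = labels == c
            if sel.any():
                centers_yx[c] = (yy[sel].mean(), xx[sel].mean())
                centers_c[c] = color[sel].reshape(-1, color.shape[-1]).mean(axis=0)

    labels = _enforce_connectivity(labels)
    _, labels = np.unique(labels, return_inverse=True)
    return labels.reshape(h, w)


def _enforce_connectivity(labels: np.ndarray) -> np.ndarray:
    """Keep each segment's largest connected component; reattach fragments
    to the segment of the nearest retained pixel."""
    final = np.full(labels.shape, -1, dtype=int)
    for c in np.unique(labels):
        comp, n = ndimage.label(labels == c)
        if n == 0:
            continue
        sizes = np.bincount(comp.ravel())[1:]
        final[comp == (np.argmax(sizes) + 1)] = c
    if (final == -1).any():
        _, (ny, nx) = ndimage.distance_transform_edt(final == -1, return_indices=True)
        orphan = final == -1
        final[orphan] = final[ny[orphan], nx[orphan]]
    return final


def _contrast_normalize(gray: np.ndarray, threshold: float) -> np.ndarray:
    """Piecewise-linear stretch mapping the Otsu threshold to mid-gray.

    Centering the two Otsu classes around 0.5 makes the downstream
    superpixel/k-means split insensitive to overall staining brightness.
    """
    lo, hi = float(gray.min()), float(gray.max())
    out = np.empty_like(gray)
    below = gray <= threshold
    denom_lo = max(threshold - lo, 1e-12)
    denom_hi = max(hi - threshold, 1e-12)
    out[below] = 0.5 * (gray[below] - lo) / denom_lo
    out[~below] = 0.5 + 0.5 * (gray[~below] - threshold) / denom_hi
    return out


def _drop_small_components(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Remove connected True components smaller than ``min_area`` pixels."""
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask
    areas = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(areas >= min_area) + 1
    return np.isin(labels, keep)


def _fill_small_holes(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Fill enclosed background holes smaller than ``min_area`` pixels."""
    labels, n = ndimage.label(~mask)
    if n == 0:
        return mask
    border = np.zeros(n + 1, dtype=bool)
    for edge in (labels[0], labels[-1], labels[:, 0], labels[:, -1]):
        border[np.unique(edge)] = True
    areas = np.bincount(labels.ravel())
    fill = np.flatnonzero((areas < min_area) & ~border)
    fill = fill[fill > 0]
    return mask | np.isin(labels, fill)


def compute_tissue_mask(
    img: SectionImage,
    n_segments: int = 1000,
    compactness: float = 10.0,
    blur_sigma: float = 2.0,
    target_width: int = 400,
    seed: int = 0,
) -> TissueMask:
    """Segment tissue from array background.

    Pipeline: downscale -> grayscale -> Otsu-referenced contrast
    normalization -> Gaussian blur -> SLIC superpixels -> k-means (k = 2) on
    per-superpixel mean features -> tissue-class identification -> hole
    filling and speck removal below 1% of the frame area.

    The tissue class is the k-means cluster with both the lower mean
    luminance and the lower fraction of border-touching superpixels
    (stained tissue is dark and interior); if the two cues disagree,
    luminance decides.
    """
    work = downscale_image(img, target_width=target_width)
    gray = work.grayscale()
    thr = otsu_threshold(gray)  # raises DegenerateImageError on flat input
    norm = _contrast_normalize(gray, thr)
    blurred_rgb = np.stack([
        ndimage.gaussian_filter(work.pixels[:, :, c], sigma=blur_sigma) for c in range(3)
    ], axis=-1)

    h, w = work.shape
    n_segments = min(n_segments, h * w)
    slic_input = SectionImage(work.section_id, blurred_rgb, work.scale)
    labels = slic_superpixels(slic_input, n_segments=n_segments,
                              compactness=compactness, seed=seed)
    n_labels = labels.max() + 1

    # Per-superpixel features: mean normalized gray + mean RGB, taken from
    # the unblurred rasters — the blur exists to stabilize superpixel
    # boundaries, and blurred features would bleed background into thin
    # tissue margins.
    flat = labels.ravel()
    counts = np.bincount(flat, minlength=n_labels).astype(float)
    feat_gray = np.bincount(flat, weights=norm.ravel(), minlength=n_labels) / counts
    feats = [feat_gray]
    for c in range(3):
        feats.append(np.bincount(flat, weights=work.pixels[:, :, c].ravel(),
                                 minlength=n_labels) / counts)
    features = np.stack(feats, axis=1)

    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(features)
    assign = km.labels_

    border = np.zeros(n_labels, dtype=bool)
    for edge in (labels[0], labels[-1], labels[:, 0], labels[:, -1]):
        border[np.unique(edge)] = True
    lum = work.grayscale().ravel()
    cluster_lum = np.array([
        lum[np.isin(flat, np.flatnonzero(assign == c))].mean() for c in (0, 1)
    ])
    cluster_border = np.array([
        border[assign == c].mean() for c in (0, 1)
    ])
    darker = int(np.argmin(cluster_lum))
    more_interior = int(np.argmin(cluster_border))
    tissue_cluster = darker if darker == more_interior else darker

    mask = np.isin(labels, np.flatnonzero(assign == tissue_cluster))
    # The pipeline assumes stained tissue on a light array background, so
    # pixels below the global Otsu threshold are tissue by definition; the
    # union guards against k-means splitting hairline variation when nearly
    # the whole frame is tissue.
    mask |= gray < thr
    min_area = max(1, int(0.01 * h * w))
    mask = _fill_small_holes(mask, min_area)
    mask = _drop_small_components(mask, min_area)
    if not mask.any() or mask.all():
        raise DegenerateImageError("segmentation produced a single class")
    return TissueMask(section_id=img.section_id, pixels=mask, source_scale=work.scale)
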