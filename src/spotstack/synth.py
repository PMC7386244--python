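"""Seeded synthetic sections for end-to-end testing without downloads.

Generates every ingredient of a spot-array experiment with known ground
truth: stained-section-like images (a smooth pink tissue blob with dark
nuclei on a near-white background), hexagonal capture lattices at 100 um
center-to-center spacing, spatially patterned negative-binomial counts with
planted factor structure, and rigid misalignments between serial sections.
Everything is reproducible bitwise from ``(parameters, seed)``.

The negative binomial is parameterized by mean mu and dispersion theta with
variance ``mu + mu^2 / theta``, matching the Pearson-residual model used for
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import ndimage

from .datamodel import CountMatrix, RigidTransform, STDataset, SectionImage, TissueMask
from .spotgraph import ROW_PITCH, hex_positions_um

__all__ = [
    "SyntheticTruth",
    "make_hex_grid",
    "simulate_section_image",
    "simulate_counts",
    "planted_pattern_expression",
    "perturb_section",
    "simulate_dataset",
    "write_spaceranger_fixture",
]


@dataclass
class SyntheticTruth:
    """Ground truth bundled with each generator's output."""

    seed: int
    true_mask: TissueMask | None = None
    nuclei_centers: np.ndarray | None = None
    true_transforms: list = field(default_factory=list)
    factor_patterns: np.ndarray | None = None
    factor_gene_sets: dict = field(default_factory=dict)


def make_hex_grid(rows: int, cols: int, spacing_um: float = 100.0,
                  section_id: str = "S1") -> pd.DataFrame:
    """``rows x cols`` spot table on a hexagonal lattice.

    Odd rows are offset half a spacing in x; the row pitch is
    spacing * sqrt(3)/2, so the nearest-neighbor distance is exactly
    ``spacing_um`` and interior spots have six neighbors within 1.5x the
    spacing.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    rr = rr.ravel()
    cc = cc.ravel()
    x = (cc + 0.5 * (rr % 2)) * spacing_um
    y = rr * spacing_um * ROW_PITCH
    return pd.DataFrame({
        "barcode": [f"spot-{r}-{c}" for r, c in zip(rr, cc)],
        "section_id": section_id,
        "array_row": rr.astype(float),
        "array_col": cc.astype(float),
        "px_x": x,
        "px_y": y,
        "in_tissue": True,
    })


def _smooth_noise(shape, sigma, rng):
    field_ = rng.standard_normal(shape)
    return ndimage.gaussian_filter(field_, sigma=sigma)


def simulate_section_image(
    width: int = 256,
    height: int = 256,
    blob_area_fraction: float = 0.4,
    blob_smoothness: float = 0.15,
    n_nuclei: int = 100,
    nucleus_radius: float = 2.0,
    seed: int = 0,
    section_id: str = "S1",
):
    """Stained-section-like image with known tissue mask and nuclei centers.

    The tissue blob is a low-frequency Gaussian random field thresholded at
    the ``1 - blob_area_fraction`` quantile, so the true mask covers the
    requested area fraction by construction. Tissue pixels are pink with
    mild texture, the background is near-white with speckle, and nuclei are
    dark purple disks dropped uniformly inside the blob.

    Returns ``(SectionImage, SyntheticTruth)`` with the true mask and the
    nuclei centers (x, y).
    """
    if width < 64 or height < 64:
        raise ValueError("image must be at least 64 x 64")
    rng = np.random.default_rng(seed)
    sigma = blob_smoothness * min(width, height)
    field_ = _smooth_noise((height, width), sigma, rng)
    thr = np.quantile(field_, 1.0 - blob_area_fraction)
    blob = field_ > thr

    img = np.empty((height, width, 3))
    img[:] = 0.96 + 0.02 * rng.standard_normal((height, width, 1))  # background speckle
    tissue_color = np.array([0.87, 0.62, 0.72])  # eosin pink
    texture = 0.05 * _smooth_noise((height, width), 2.0, rng)
    for c in range(3):
        channel = img[:, :, c]
        channel[blob] = tissue_color[c] + texture[blob]

    centers = np.empty((0, 2))
    if n_nuclei > 0 and blob.any():
        ys, xs = np.nonzero(blob)
        # keep nuclei away from the blob edge so disks stay inside tissue
        interior = ndimage.binary_erosion(blob, iterations=int(np.ceil(nucleus_radius)) + 1)
        if interior.any():
            ys, xs = np.nonzero(interior)
        pick = rng.choice(len(ys), size=min(n_nuclei, len(ys)), replace=False)
        centers = np.column_stack([xs[pick], ys[pick]]).astype(float)
        yy, xx = np.mgrid[0:height, 0:width]
        nucleus_color = np.array([0.30, 0.18, 0.42])  # hematoxylin purple
        for cx, cy in centers:
            disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= nucleus_radius**2
            for c in range(3):
                img[:, :, c][disk] = nucleus_color[c]

    img = np.clip(img, 0.0, 1.0)
    image = SectionImage(section_id=section_id, pixels=img, scale=1.0)
    truth = SyntheticTruth(
        seed=seed,
        true_mask=TissueMask(section_id=section_id, pixels=blob, source_scale=1.0),
        nuclei_centers=centers,
    )
    return image, truth


def _gaussian_bump_patterns(pos: np.ndarray, k: int, rng,
                            width_fraction: float = 0.25) -> np.ndarray:
    """k spatial patterns in [0, 1]: Gaussian bumps on the lattice.

    Bump centers are drawn by greedy farthest-point selection among random
    candidates so the k planted patterns are distinct — coincident centers
    would make the planted ground truth unidentifiable.
    """
    lo = pos.min(axis=0)
    hi = pos.max(axis=0)
    extent = float(np.linalg.norm(hi - lo))
    sigma = max(width_fraction * extent, 1e-9)
    centers = [lo + rng.uniform(0.1, 0.9, size=2) * (hi - lo)]
    for _ in range(1, k):
        cands = lo + rng.uniform(0.1, 0.9, size=(64, 2)) * (hi - lo)
        dmin = np.min(
            np.linalg.norm(cands[:, None, :] - np.asarray(centers)[None, :, :], axis=2),
            axis=1,
        )
        centers.append(cands[np.argmax(dmin)])
    patterns = np.empty((k, len(pos)))
    for f, center in enumerate(centers):
        d2 = ((pos - center) ** 2).sum(axis=1)
        p = np.exp(-d2 / (2 * sigma**2))
        patterns[f] = p / p.max()
    return patterns


def _nb_sample(mean: np.ndarray, theta: float, rng) -> np.ndarray:
    """NB(mu, theta) with variance mu + mu^2/theta, via gamma-Poisson."""
    mean = np.maximum(mean, 1e-12)
    lam = rng.gamma(shape=theta, scale=mean / theta)
    return rng.poisson(lam)


def simulate_counts(
    spots: pd.DataFrame,
    n_genes: int = 200,
    k: int = 4,
    effect: float = 3.0,
    theta: float = 10.0,
    baseline_mean: float = 2.0,
    genes_per_factor: int | None = None,
    spacing_um: float = 100.0,
    seed: int = 0,
):
    """Spatially patterned NB counts with k planted factors.

    Each factor is a Gaussian bump over the lattice and owns a disjoint gene
    set (default ``n_genes // (2k)`` genes each) whose expected expression is
    ``baseline * (1 + effect * pattern)``; the remaining genes are
    pattern-free. Per-gene baselines are log-normal around
    ``baseline_mean``. Counts are NB(mu, theta).

    Returns ``(CountMatrix, SyntheticTruth)`` where the truth records the
    k x spots pattern matrix and the factor -> gene-set map.
    """
    if n_genes < 10 * k:
        raise ValueError("need n_genes >= 10 * k")
    rng = np.random.default_rng(seed)
    pos = hex_positions_um(spots, spacing_um)
    patterns = _gaussian_bump_patterns(pos, k, rng)
    if genes_per_factor is None:
        genes_per_factor = n_genes // (2 * k)
    gene_sets = {}
    mean = np.empty((n_genes, len(spots)))
    baselines = baseline_mean * rng.lognormal(mean=0.0, sigma=0.5, size=n_genes)
    next_gene = 0
    names = [f"gene{g:04d}" for g in range(n_genes)]
    for f in range(k):
        members = list(range(next_gene, next_gene + genes_per_factor))
        gene_sets[f] = {names[g] for g in members}
        for g in members:
            mean[g] = baselines[g] * (1.0 + effect * patterns[f])
        next_gene += genes_per_factor
    for g in range(next_gene, n_genes):
        mean[g] = baselines[g]

    values = _nb_sample(mean, theta, rng)
    counts = CountMatrix(
        genes=names,
        spots=list(zip(spots["barcode"], spots["section_id"])),
        values=sp.csr_matrix(values),
    )
    truth = SyntheticTruth(seed=seed, factor_patterns=patterns,
                           factor_gene_sets=gene_sets)
    return counts, truth


def planted_pattern_expression(
    spots: pd.DataFrame,
    n_null: int = 999,
    effect: float = 3.0,
    theta: float = 10.0,
    baseline_mean: float = 2.0,
    spacing_um: float = 100.0,
    seed: int = 0,
):
    """One Gaussian-bump gene among spatially permuted null copies.

    Gene 0 carries a smooth spatial bump; each of the ``n_null`` remaining
    genes is an independent spatial permutation of gene 0's counts — same
    marginal distribution, no spatial structure. The fixture isolates
    spatial signal from expression-level differences for ranking-power
    studies.

    Returns ``(expr, gene_names)`` with the patterned gene first.
    """
    rng = np.random.default_rng(seed)
    pos = hex_positions_um(spots, spacing_um)
    pattern = _gaussian_bump_patterns(pos, 1, rng)[0]
    mean = baseline_mean * (1.0 + effect * pattern)
    signal = _nb_sample(mean, theta, rng).astype(float)
    expr = np.empty((n_null + 1, len(spots)))
    expr[0] = signal
    for g in range(n_null):
        expr[g + 1] = rng.permutation(signal)
    names = ["bump"] + [f"null{g:04d}" for g in range(n_null)]
    return expr, names


def perturb_section(mask: TissueMask, angle_deg: float = 0.0,
                    shift_px=(0.0, 0.0), reflect: bool = False,
                    seed: int = 0):
    """Apply a known rigid transform to a mask (nearest-neighbor warp).

    Rotation/reflection act about the image center. Returns the warped mask
    together with the exact :class:`RigidTransform` used, for registration
    ground truth. A transform that pushes the entire blob out of frame is an
    error.
    """
    if not mask.pixels.any() or mask.pixels.all():
        raise ValueError("mask must contain both classes")
    h, w = mask.shape
    center = ((w - 1) / 2.0, (h - 1) / 2.0)
    T = RigidTransform.from_parts(angle_deg=angle_deg, shift=shift_px,
                                  reflect=reflect, center=center)
    from .registration import warp_image_backward

    warped = warp_image_backward(mask.pixels.astype(float), T,
                                 out_shape=(h, w), fill=0.0, order=0)
    warped = warped > 0.5
    if not warped.any():
        raise ValueError("transform pushed the tissue blob out of frame")
    return TissueMask(section_id=mask.section_id, pixels=warped,
                      source_scale=mask.source_scale), T


_PRESETS = {
    "small": dict(rows=12, cols=12, n_genes=120, k=3, n_sections=2,
                  width=192, height=192, n_nuclei=60),
    "medium": dict(rows=20, cols=25, n_genes=400, k=4, n_sections=3,
                   width=320, height=320, n_nuclei=150),
}


def simulate_dataset(preset: str = "small", seed: int = 0,
                     effect: float = 3.0, theta: float = 10.0):
    """Full multi-section synthetic experiment in one call.

    Builds ``n_sections`` sections sharing one hex lattice and planted
    factor structure, each with its own simulated image; sections after the
    first carry known rigid misalignments recorded in the returned truth.

    Returns ``(STDataset, SyntheticTruth)``.
    """
    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}")
    p = _PRESETS[preset]
    rng = np.random.default_rng(seed)
    sections = []
    truths = []
    images = {}
    for s in range(p["n_sections"]):
        sid = f"S{s + 1}"
        sub_seed = int(rng.integers(0, 2**31 - 1))
        spots = make_hex_grid(p["rows"], p["cols"], section_id=sid)
        counts, truth_c = simulate_counts(
            spots, n_genes=p["n_genes"], k=p["k"], effect=effect, theta=theta,
            seed=sub_seed,
        )
        image, truth_i = simulate_section_image(
            width=p["width"], height=p["height"], n_nuclei=p["n_nuclei"],
            seed=seed,  # same base section shape for every slice
            section_id=sid,
        )
        if s > 0:
            angle = float(rng.uniform(-20, 20))
            shift = tuple(rng.uniform(-15, 15, size=2))
            warped_mask, T = perturb_section(truth_i.true_mask, angle, shift)
            from .registration import warp_image_backward

            warped = warp_image_backward(image, T, out_shape=image.shape)
            image = SectionImage(sid, warped.pixels, image.scale)
            truth_i.true_mask = TissueMask(sid, warped_mask.pixels, 1.0)
            truth_i.true_transforms = [T]
        # spot pixel coordinates: place the lattice inside the frame
        margin = 12
        spots = spots.copy()
        pos = hex_positions_um(spots, 100.0)
        span = pos.max(axis=0) - pos.min(axis=0)
        scale_fit = min((p["width"] - 2 * margin) / max(span[0], 1),
                        (p["height"] - 2 * margin) / max(span[1], 1))
        spots["px_x"] = margin + (pos[:, 0] - pos[:, 0].min()) * scale_fit
        spots["px_y"] = margin + (pos[:, 1] - pos[:, 1].min()) * scale_fit
        ds = STDataset(counts, spots, {sid: image}, spacing_um=100.0)
        sections.append(ds)
        truth_c.true_mask = truth_i.true_mask
        truth_c.nuclei_centers = truth_i.nuclei_centers
        truth_c.true_transforms = truth_i.true_transforms
        truths.append(truth_c)
        images[sid] = image

    from .datamodel import concat_datasets

    dataset = concat_datasets(sections)
    truth = SyntheticTruth(
        seed=seed,
        factor_patterns=truths[0].factor_patterns,
        factor_gene_sets=truths[0].factor_gene_sets,
        true_transforms=[t.true_transforms[0] if t.true_transforms else RigidTransform.identity()
                         for t in truths],
        nuclei_centers=truths[0].nuclei_centers,
        true_mask=truths[0].true_mask,
    )
    truth.per_section = truths
    return dataset, truth


def write_spaceranger_fixture(out_dir, preset: str = "small", seed: int = 0):
    """Write a complete synthetic experiment in Space Ranger layout.

    One subdirectory per section (mtx + TSVs + positions CSV + scale factors
    + PNG image) plus a manifest, exercising the reader end to end.
    """
    from .io import write_bundle

    dataset, truth = simulate_dataset(preset=preset, seed=seed)
    write_bundle(dataset, out_dir)
    return dataset, truth
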