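"""Shared data model for spatial transcriptomics sections.

A dataset couples a genes x spots count matrix with a spot table (barcode,
array coordinates on the hexagonal capture lattice, full-resolution pixel
coordinates, tissue flag) and, optionally, one stained-section raster image
per section. Pixel coordinates follow the raster convention: ``px_x`` is the
pixel column, ``px_y`` the pixel row, origin at the top-left, 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

SPOT_COLUMNS = ["barcode", "section_id", "array_row", "array_col", "px_x", "px_y", "in_tissue"]


@dataclass
class CountMatrix:
    """Genes x spots matrix of non-negative integer UMI counts.

    ``values`` is kept sparse (CSR); ``spots`` holds ``(barcode, section_id)``
    pairs in the same column order as the dataset's spot table.
    """

    genes: list
    spots: list
    values: sp.csr_matrix

    def __post_init__(self):
        self.values = sp.csr_matrix(self.values)
        if self.values.shape != (len(self.genes), len(self.spots)):
            raise ValueError(
                f"count matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.spots)} spots"
            )
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())


@dataclass
class SectionImage:
    """Raster image of a stained section sharing a frame with spot pixels.

    ``scale`` is raster pixels per full-resolution pixel, so multiplying a
    spot's full-resolution coordinates by ``scale`` lands on this raster.
    """

    section_id: str
    pixels: np.ndarray  # H x W x 3 float in [0, 1]
    scale: float

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim == 2:
            self.pixels = np.repeat(self.pixels[:, :, None], 3, axis=2)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("image must be H x W x 3")
        if not self.scale > 0:
            raise ValueError("scale must be positive")

    @property
    def shape(self):
        return self.pixels.shape[:2]

    def grayscale(self) -> np.ndarray:
        """Luminance (0.299 R + 0.587 G + 0.114 B) in [0, 1]."""
        return self.pixels @ np.array([0.299, 0.587, 0.114])


@dataclass
class TissueMask:
    """Binary tissue raster (True = tissue) in a working-image frame."""

    section_id: str
    pixels: np.ndarray  # H x W bool
    source_scale: float

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class STDataset:
    """One or more sections: counts + spot table + images + lattice spacing."""

    counts: CountMatrix
    spots: pd.DataFrame
    images: dict = field(default_factory=dict)
    spacing_um: float = 100.0

    def __post_init__(self):
        missing = [c for c in SPOT_COLUMNS if c not in self.spots.columns]
        if missing:
            raise ValueError(f"spot table missing columns {missing}")
        if not self.spacing_um > 0:
            raise ValueError("spacing_um must be positive")
        self.spots = self.spots.reset_index(drop=True)
        key = list(zip(self.spots["barcode"], self.spots["section_id"]))
        if len(set(key)) != len(key):
            raise ValueError("(barcode, section_id) pairs must be unique")
        if key != list(self.counts.spots):
            raise ValueError("spot table order does not match count matrix columns")
        if self.images:
            for sid in self.spots["section_id"].unique():
                if sid not in self.images:
                    raise ValueError(f"no image for section {sid!r}")

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    @property
    def n_genes(self) -> int:
        return self.counts.n_genes

    @property
    def section_ids(self) -> list:
        return list(dict.fromkeys(self.spots["section_id"]))

    def subset_spots(self, index: np.ndarray) -> "STDataset":
        """Dataset restricted to the spot positions in ``index`` (kept order)."""
        index = np.asarray(index)
        spots = self.spots.iloc[index]
        counts = CountMatrix(
            genes=list(self.counts.genes),
            spots=[self.counts.spots[i] for i in index],
            values=self.counts.values[:, index],
        )
        images = {s: self.images[s] for s in spots["section_id"].unique() if s in self.images}
        return STDataset(counts, spots, images, self.spacing_um)

    def in_tissue(self) -> "STDataset":
        """Spots flagged as under tissue (the default analysis set)."""
        idx = np.flatnonzero(self.spots["in_tissue"].to_numpy().astype(bool))
        return self.subset_spots(idx)


@dataclass
class RigidTransform:
    """3x3 homogeneous plane transform with orthonormal linear part.

    The linear block is a rotation (det = +1) or a rotation composed with a
    reflection (det = -1); the transform therefore preserves all pairwise
    distances. Acts on (x, y) coordinates.
    """

    matrix: np.ndarray
    is_reflection: bool = False
    converged: bool = True
    rmsd: float = 0.0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise ValueError("transform matrix must be 3x3")
        R = self.matrix[:2, :2]
        if not np.allclose(R.T @ R, np.eye(2), atol=1e-8):
            raise ValueError("linear part is not orthonormal")
        if not np.allclose(self.matrix[2], [0.0, 0.0, 1.0], atol=1e-12):
            raise ValueError("bottom row must be (0, 0, 1)")
        det = float(np.linalg.det(R))
        if self.is_reflection != (det < 0):
            raise ValueError(f"is_reflection={self.is_reflection} inconsistent with det={det:+.3f}")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), False)

    @classmethod
    def from_parts(cls, angle_deg: float = 0.0, shift: tuple = (0.0, 0.0),
                   reflect: bool = False, center: tuple = (0.0, 0.0)) -> "RigidTransform":
        """Reflection about the vertical axis (x -> -x), then rotation, both
        about ``center``, then translation by ``shift``."""
        a = np.deg2rad(angle_deg)
        R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        if reflect:
            R = R @ np.diag([-1.0, 1.0])
        c = np.asarray(center, dtype=float)
        t = c - R @ c + np.asarray(shift, dtype=float)
        M = np.eye(3)
        M[:2, :2] = R
        M[:2, 2] = t
        return cls(M, reflect)

    @property
    def rotation_deg(self) -> float:
        """Rotation angle of the proper-rotation part, in (-180, 180]."""
        R = self.matrix[:2, :2]
        if self.is_reflection:
            R = R @ np.diag([-1.0, 1.0])
        return float(np.rad2deg(np.arctan2(R[1, 0], R[0, 0])))

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:2, 2].copy()

    def inverse(self) -> "RigidTransform":
        return RigidTransform(np.linalg.inv(self.matrix), self.is_reflection,
                              self.converged, self.rmsd)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform applying ``other`` first, then ``self``."""
        return RigidTransform(self.matrix @ other.matrix,
                              self.is_reflection != other.is_reflection)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        from .registration import apply_rigid

        return apply_rigid(points, self)


def concat_datasets(ds_list) -> STDataset:
    """Concatenate sections into one dataset.

    Gene universes are unioned (first-seen order) with zeros where a gene is
    absent from a section; spot order is the input concatenation order.
    Duplicate section identifiers and mismatched lattice spacings are
    rejected.
    """
    ds_list = list(ds_list)
    if not ds_list:
        raise ValueError("need at least one dataset")
    spacing = ds_list[0].spacing_um
    for ds in ds_list[1:]:
        if ds.spacing_um != spacing:
            raise ValueError("datasets disagree on spacing_um")
    seen_sections = set()
    for ds in ds_list:
        for sid in ds.section_ids:
            if sid in seen_sections:
                raise ValueError(f"duplicate section_id {sid!r}")
            seen_sections.add(sid)

    genes: list = []
    gene_index: dict = {}
    for ds in ds_list:
        for g in ds.counts.genes:
            if g not in gene_index:
                gene_index[g] = len(genes)
                genes.append(g)

    blocks = []
    for ds in ds_list:
        rows = np.array([gene_index[g] for g in ds.counts.genes])
        coo = ds.counts.values.tocoo()
        blocks.append(sp.coo_matrix(
            (coo.data, (rows[coo.row], coo.col)),
            shape=(len(genes), ds.counts.n_spots),
        ))
    values = sp.hstack(blocks).tocsr()
    spots = pd.concat([ds.spots for ds in ds_list], ignore_index=True)
    all_spot_ids = [s for ds in ds_list for s in ds.counts.spots]
    images = {}
    for ds in ds_list:
        images.update(ds.images)
    counts = CountMatrix(genes=genes, spots=all_spot_ids, values=values)
    return STDataset(counts, spots, images, spacing)
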