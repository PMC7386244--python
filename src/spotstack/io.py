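"""Readers and writers for Visium-style and legacy spot-array data.

Supported inputs are the Space Ranger output layout (MatrixMarket counts +
features/barcodes TSV + a ``spatial/`` directory with a positions CSV,
scale-factors JSON and section images) and legacy spot-array count tables
whose column headers encode array coordinates as ``"x_y"``. Datasets are
persisted as a directory bundle in the same Space Ranger layout (one
subdirectory per section plus a small JSON manifest), so a written bundle
round-trips through :func:`read_spaceranger`.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from PIL import Image

from .datamodel import CountMatrix, STDataset, SectionImage, concat_datasets

__all__ = [
    "read_spaceranger",
    "read_legacy_st",
    "concat_datasets",
    "write_bundle",
    "read_bundle",
]

_POSITION_COLUMNS = [
    "barcode", "in_tissue", "array_row", "array_col",
    "pxl_row_in_fullres", "pxl_col_in_fullres",
]


class MissingInputError(FileNotFoundError):
    """A required file of the Space Ranger layout is absent or unreadable."""


def _find(dir: Path, names, what: str) -> Path:
    for name in names:
        for cand in (dir / name, dir / f"{name}.gz"):
            if cand.exists():
                return cand
    raise MissingInputError(f"missing input: no {what} found under {dir} (tried {names})")


def _open_maybe_gzip(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_tsv_column(path: Path, column: int = 0) -> list:
    with _open_maybe_gzip(path) as fh:
        return [line.rstrip("\n").split("\t")[column] for line in fh if line.strip()]


def _read_positions(path: Path) -> pd.DataFrame:
    """Positions CSV, accepting both the headerless v1 dialect and the
    headered v2 dialect (detected from the first row)."""
    with _open_maybe_gzip(path) as fh:
        first = fh.readline()
    header = 0 if first.lower().startswith("barcode") else None
    df = pd.read_csv(path, header=header)
    if df.shape[1] < 6:
        raise MissingInputError(f"positions file {path} has {df.shape[1]} columns, expected 6")
    df = df.iloc[:, :6]
    df.columns = _POSITION_COLUMNS
    return df


def read_spaceranger(
    dir,
    section_id: str,
    resolution: str = "lowres",
    filter_to_matrix: bool = True,
) -> STDataset:
    """Load one section from a Space Ranger-style output directory.

    Parameters
    ----------
    dir
        Directory holding ``matrix.mtx[.gz]``, ``features.tsv[.gz]``,
        ``barcodes.tsv[.gz]`` (possibly inside a ``filtered_feature_bc_matrix``
        subdirectory) and a ``spatial/`` subdirectory with the positions CSV,
        ``scalefactors_json.json`` and at least one section image.
    section_id
        Identifier attached to every spot and to the image.
    resolution
        ``"lowres"`` (default) or ``"hires"``: which image and matching scale
        factor to attach.
    filter_to_matrix
        Keep only barcodes present in both the matrix and the positions file
        (default). With ``False``, any mismatch raises instead.

    Returns
    -------
    STDataset
        Spot pixel coordinates are in full-resolution units; the attached
        image carries the scale factor that maps them onto its raster.
    """
    dir = Path(dir)
    matrix_dirs = [dir, dir / "filtered_feature_bc_matrix", dir / "raw_feature_bc_matrix"]
    matrix_dir = next(
        (d for d in matrix_dirs
         if d.is_dir() and any((d / n).exists() or (d / f"{n}.gz").exists()
                               for n in ("matrix.mtx",))),
        None,
    )
    if matrix_dir is None:
        raise MissingInputError(f"missing input: no matrix.mtx[.gz] under {dir}")
    matrix_path = _find(matrix_dir, ["matrix.mtx"], "count matrix")
    features_path = _find(matrix_dir, ["features.tsv", "genes.tsv"], "features TSV")
    barcodes_path = _find(matrix_dir, ["barcodes.tsv"], "barcodes TSV")
    spatial = dir / "spatial"
    if not spatial.is_dir():
        raise MissingInputError(f"missing input: no spatial/ directory under {dir}")
    positions_path = _find(
        spatial, ["tissue_positions_list.csv", "tissue_positions.csv"], "positions CSV"
    )
    scalefactors_path = _find(spatial, ["scalefactors_json.json"], "scale-factors JSON")

    try:
        values = sp.csr_matrix(scipy.io.mmread(_open_maybe_gzip(matrix_path)))
    except Exception as exc:  # noqa: BLE001 - surfaced with file name
        raise MissingInputError(f"missing input: cannot parse matrix {matrix_path}: {exc}") from exc
    genes = _read_tsv_column(features_path, 0)
    barcodes = _read_tsv_column(barcodes_path, 0)
    if values.shape != (len(genes), len(barcodes)):
        raise MissingInputError(
            f"matrix shape {values.shape} does not match {len(genes)} features "
            f"x {len(barcodes)} barcodes"
        )

    positions = _read_positions(positions_path)
    pos_barcodes = set(positions["barcode"])
    keep = [i for i, b in enumerate(barcodes) if b in pos_barcodes]
    if not filter_to_matrix and (len(keep) != len(barcodes) or len(pos_barcodes) != len(barcodes)):
        raise ValueError(
            f"barcode mismatch: matrix has {len(barcodes)} barcodes, "
            f"positions file has {len(pos_barcodes)}"
        )
    barcodes = [barcodes[i] for i in keep]
    values = values[:, keep]
    positions = positions.set_index("barcode").loc[barcodes].reset_index()

    with open(scalefactors_path) as fh:
        scalefactors = json.load(fh)
    image_names = {
        "lowres": ("tissue_lowres_image.png", "tissue_lowres_image.tif"),
        "hires": ("tissue_hires_image.png", "tissue_hires_image.tif"),
    }
    if resolution not in image_names:
        raise ValueError(f"resolution must be 'lowres' or 'hires', got {resolution!r}")
    image_path = _find(spatial, list(image_names[resolution]), f"{resolution} image")
    pixels = np.asarray(Image.open(image_path).convert("RGB"), dtype=float) / 255.0
    scale = float(scalefactors[f"tissue_{resolution}_scalef"])
    image = SectionImage(section_id=section_id, pixels=pixels, scale=scale)

    spots = pd.DataFrame({
        "barcode": positions["barcode"],
        "section_id": section_id,
        "array_row": positions["array_row"].astype(float),
        "array_col": positions["array_col"].astype(float),
        "px_x": positions["pxl_col_in_fullres"].astype(float),
        "px_y": positions["pxl_row_in_fullres"].astype(float),
        "in_tissue": positions["in_tissue"].astype(int).astype(bool),
    })
    counts = CountMatrix(
        genes=genes,
        spots=[(b, section_id) for b in barcodes],
        values=values,
    )
    return STDataset(counts, spots, {section_id: image}, spacing_um=100.0)


def read_legacy_st(counts_path, section_id: str, spacing_um: float = 100.0) -> STDataset:
    """Load a legacy spot-array count table with ``"x_y"`` spot headers.

    The table has genes on one axis and spots on the other; spot headers
    encode array coordinates as two ``_``-separated numbers (fractional
    values are accepted — adjusted legacy coordinates use them). Pixel
    coordinates are synthesized as array coordinate x spacing; no image is
    attached.
    """
    df = pd.read_csv(counts_path, sep=None, engine="python", index_col=0)
    headers = [str(c) for c in df.columns]

    def parse(header: str):
        parts = header.split("_")
        if len(parts) != 2:
            raise ValueError(f"cannot parse spot header {header!r} as 'x_y'")
        try:
            return float(parts[0]), float(parts[1])
        except ValueError:
            raise ValueError(f"cannot parse spot header {header!r} as 'x_y'") from None

    def parses(header: str) -> bool:
        try:
            parse(header)
            return True
        except ValueError:
            return False

    # Spots may be rows instead of columns: transpose only when the row
    # index parses as coordinates and the column headers do not.
    if not parses(headers[0]) and parses(str(df.index[0])):
        df = df.T
        headers = [str(c) for c in df.columns]
    coords = [parse(h) for h in headers]
    xs = np.array([c[0] for c in coords])
    ys = np.array([c[1] for c in coords])
    spots = pd.DataFrame({
        "barcode": headers,
        "section_id": section_id,
        "array_row": ys,
        "array_col": xs,
        "px_x": xs * spacing_um,
        "px_y": ys * spacing_um,
        "in_tissue": True,
    })
    counts = CountMatrix(
        genes=[str(g) for g in df.index],
        spots=[(h, section_id) for h in headers],
        values=sp.csr_matrix(df.to_numpy(dtype=float)),
    )
    return STDataset(counts, spots, {}, spacing_um=spacing_um)


def write_bundle(dataset: STDataset, out_dir) -> Path:
    """Write a dataset as a directory bundle (Space Ranger layout per section).

    Layout: ``<out>/manifest.json`` plus one ``<out>/<section_id>/`` subtree
    per section with ``matrix.mtx``, ``features.tsv``, ``barcodes.tsv`` and a
    ``spatial/`` directory; uncompressed, text except the PNG images.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"spacing_um": dataset.spacing_um, "sections": []}
    for sid in dataset.section_ids:
        idx = np.flatnonzero((dataset.spots["section_id"] == sid).to_numpy())
        sub = dataset.subset_spots(idx)
        sdir = out_dir / str(sid)
        (sdir / "spatial").mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(sdir / "matrix.mtx", sub.counts.values.astype(int))
        with open(sdir / "features.tsv", "w") as fh:
            for g in sub.counts.genes:
                fh.write(f"{g}\t{g}\tGene Expression\n")
        with open(sdir / "barcodes.tsv", "w") as fh:
            for b, _ in sub.counts.spots:
                fh.write(f"{b}\n")
        pos = pd.DataFrame({
            "barcode": sub.spots["barcode"],
            "in_tissue": sub.spots["in_tissue"].astype(int),
            "array_row": sub.spots["array_row"],
            "array_col": sub.spots["array_col"],
            "pxl_row_in_fullres": sub.spots["px_y"],
            "pxl_col_in_fullres": sub.spots["px_x"],
        })
        pos.to_csv(sdir / "spatial" / "tissue_positions.csv", index=False)
        scale = 1.0
        if sid in dataset.images:
            img = dataset.images[sid]
            scale = img.scale
            Image.fromarray(
                np.clip(img.pixels * 255, 0, 255).astype(np.uint8)
            ).save(sdir / "spatial" / "tissue_lowres_image.png")
        else:
            # Placeholder raster keeps the layout readable by read_spaceranger.
            Image.fromarray(np.full((16, 16, 3), 255, dtype=np.uint8)).save(
                sdir / "spatial" / "tissue_lowres_image.png"
            )
        with open(sdir / "spatial" / "scalefactors_json.json", "w") as fh:
            json.dump({"tissue_lowres_scalef": scale, "tissue_hires_scalef": scale,
                       "spot_diameter_fullres": dataset.spacing_um / 2.0}, fh)
        manifest["sections"].append(str(sid))
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out_dir


def read_bundle(bundle_dir) -> STDataset:
    """Read a bundle written by :func:`write_bundle`."""
    bundle_dir = Path(bundle_dir)
    manifest_path = bundle_dir / "manifest.json"
    if not manifest_path.exists():
        raise MissingInputError(f"missing input: {manifest_path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    sections = [
        read_spaceranger(bundle_dir / sid, sid) for sid in manifest["sections"]
    ]
    ds = concat_datasets(sections) if len(sections) > 1 else sections[0]
    ds.spacing_um = float(manifest.get("spacing_um", 100.0))
    return ds
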