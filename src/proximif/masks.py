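"""From channel images to a cell table.

The imaging-side stage of the pipeline: threshold intensity images into
binary masks, identify cells as connected components of the nuclear (DAPI)
mask marked at their centroid, and flag each cell positive for a marker
channel when the marker mask sufficiently overlaps the cell's captured
region (its nucleus component, optionally dilated to approximate the
cytoplasm).

Coordinate convention (shared package-wide): x runs along columns, y along
rows (downwards), pixel centers at ``(index + 0.5) * pixel_size_um``, so all
centroids and distances are in µm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from sklearn.base import BaseEstimator

from .simulate import MaskStack, NUCLEUS_CHANNEL


@dataclass
class BinaryMask:
    grid: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        self.grid = self.grid.astype(bool)


@dataclass
class OverlapRule:
    """How marker masks are mapped onto cells.

    ``dilation_um`` expands the nucleus component to capture cytoplasmic /
    membranous staining; a cell is positive when at least
    ``min_overlap_fraction`` of the captured region is marker-positive.
    ``min_overlap_fraction=None`` means any overlap (>= 1 pixel).
    """

    dilation_um: float = 3.0
    min_overlap_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.dilation_um < 0:
            raise ValueError("dilation_um must be >= 0")
        if self.min_overlap_fraction is not None and not 0 < self.min_overlap_fraction <= 1:
            raise ValueError("min_overlap_fraction must be in (0, 1]")


def threshold_channel(image: np.ndarray, threshold: float | str,
                      pixel_size_um: float = 1.0) -> BinaryMask:
    """Binarize an intensity image: pixel true iff intensity >= threshold.

    ``threshold="otsu"`` picks the threshold maximizing between-class
    variance of the image histogram; a constant image has no separable
    classes and is rejected.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D intensity image")
    if not np.isfinite(img).all() or (img < 0).any():
        raise ValueError("intensities must be finite and non-negative")
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold method {threshold!r}")
        if np.ptp(img) == 0:
            raise ValueError("constant image: Otsu thresholding has no separable classes")
        t = threshold_otsu(img)
        # skimage's convention is img > t; shift to the closed >= convention
        # by taking the smallest observed value above t as the threshold.
        t = img[img > t].min()
    else:
        t = float(threshold)
    return BinaryMask(grid=img >= t, pixel_size_um=pixel_size_um)


@dataclass
class DetectedCells:
    """Cell table plus the label image carrying each nucleus' pixel footprint."""

    cells: pd.DataFrame  # id, x_um, y_um, area_px, label
    labels: np.ndarray   # 0 = background; values match cells["label"]
    pixel_size_um: float


def detect_cells(dapi: BinaryMask, min_area_px: int = 4,
                 connectivity: int = 8) -> DetectedCells:
    """One cell per connected component of the nuclear mask.

    Components are found under 8-connectivity by default (4 available),
    centroids are placed at the mean pixel center in µm, ids follow
    raster-scan discovery order, and components below ``min_area_px``
    pixels are discarded as debris.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = np.ones((3, 3), dtype=int) if connectivity == 8 else None
    labels, n = ndimage.label(dapi.grid, structure=structure)
    px = dapi.pixel_size_um
    if n == 0:
        cells = pd.DataFrame({"id": pd.Series(dtype=np.int64),
                              "x_um": pd.Series(dtype=float),
                              "y_um": pd.Series(dtype=float),
                              "area_px": pd.Series(dtype=np.int64),
                              "label": pd.Series(dtype=np.int64)})
        return DetectedCells(cells=cells, labels=labels, pixel_size_um=px)
    idx = np.arange(1, n + 1)
    areas = ndimage.sum_labels(np.ones_like(labels), labels, idx).astype(np.int64)
    centroids = ndimage.center_of_mass(dapi.grid, labels, idx)  # (row, col)
    rows = np.array([c[0] for c in centroids])
    cols = np.array([c[1] for c in centroids])
    cells = pd.DataFrame({
        "x_um": (cols + 0.5) * px,
        "y_um": (rows + 0.5) * px,
        "area_px": areas,
        "label": idx,
    })
    cells = cells[cells["area_px"] >= min_area_px].reset_index(drop=True)
    cells.insert(0, "id", np.arange(len(cells), dtype=np.int64))
    return DetectedCells(cells=cells, labels=labels, pixel_size_um=px)


class CellDetector(BaseEstimator):
    """Estimator wrapper around :func:`detect_cells`.

    Parameters mirror the function; ``transform`` maps a nuclear
    :class:`BinaryMask` to a :class:`DetectedCells` result.
    """

    def __init__(self, min_area_px: int = 4, connectivity: int = 8):
        self.min_area_px = min_area_px
        self.connectivity = connectivity

    def fit(self, X: BinaryMask, y=None) -> "CellDetector":
        if not isinstance(X, BinaryMask):
            raise TypeError("CellDetector expects a BinaryMask")
        self.n_components_ = len(
            self.transform(X).cells)
        return self

    def transform(self, X: BinaryMask) -> DetectedCells:
        return detect_cells(X, min_area_px=self.min_area_px,
                            connectivity=self.connectivity)

    def fit_transform(self, X: BinaryMask, y=None) -> DetectedCells:
        return self.fit(X).transform(X)


def _captured_region(component: np.ndarray, dilation_um: float,
                     pixel_size_um: float) -> np.ndarray:
    """Pixels within ``dilation_um`` of the component (Euclidean, in µm)."""
    if dilation_um <= 0:
        return component
    dt = ndimage.distance_transform_edt(~component, sampling=pixel_size_um)
    return dt <= dilation_um


def assign_markers(cells: DetectedCells | pd.DataFrame, stack: MaskStack,
                   rule: OverlapRule | None = None,
                   channels: list[str] | None = None) -> pd.DataFrame:
    """Assign per-cell marker positivity from overlap with channel masks.

    ``cells`` may be a :class:`DetectedCells` (nucleus footprints are used)
    or a bare coordinate table (a disk of radius ``rule.dilation_um`` around
    the centroid is used instead, degrading to the single containing pixel
    when the dilation is smaller than a pixel). DAPI is never a marker flag.
    """
    rule = rule or OverlapRule()
    if channels is None:
        channels = [c for c in stack.channel_names if c != NUCLEUS_CHANNEL]
    missing = [c for c in channels if c not in stack.channels]
    if missing:
        raise KeyError(f"channels missing from mask stack: {missing}")

    px = stack.pixel_size_um
    nr, nc = stack.shape

    if isinstance(cells, DetectedCells):
        table = cells.cells.copy()
        labels = cells.labels
        pad = int(np.ceil(rule.dilation_um / px)) + 1
        objects = ndimage.find_objects(labels)
        regions = []
        for _, row in table.iterrows():
            lab = int(row["label"])
            sl = objects[lab - 1]
            r0 = max(0, sl[0].start - pad)
            r1 = min(nr, sl[0].stop + pad)
            c0 = max(0, sl[1].start - pad)
            c1 = min(nc, sl[1].stop + pad)
            comp = labels[r0:r1, c0:c1] == lab
            cap = _captured_region(comp, rule.dilation_um, px)
            regions.append(((slice(r0, r1), slice(c0, c1)), cap))
    else:
        table = cells.copy()
        regions = []
        r_idx = rule.dilation_um / px
        for _, row in table.iterrows():
            ci = row["y_um"] / px - 0.5
            cj = row["x_um"] / px - 0.5
            i0 = max(0, int(np.floor(ci - r_idx)))
            i1 = min(nr, int(np.ceil(ci + r_idx)) + 1)
            j0 = max(0, int(np.floor(cj - r_idx)))
            j1 = min(nc, int(np.ceil(cj + r_idx)) + 1)
            ii = np.arange(i0, i1)[:, None]
            jj = np.arange(j0, j1)[None, :]
            cap = (ii - ci) ** 2 + (jj - cj) ** 2 <= r_idx ** 2
            if not cap.any():
                # guarantee at least the pixel containing the centroid
                pi = min(nr - 1, max(0, int(round(ci))))
                pj = min(nc - 1, max(0, int(round(cj))))
                i0, i1, j0, j1 = pi, pi + 1, pj, pj + 1
                cap = np.ones((1, 1), dtype=bool)
            regions.append(((slice(i0, i1), slice(j0, j1)), cap))

    for ch in channels:
        mask = stack[ch]
        flags = np.zeros(len(table), dtype=bool)
        for k, (window, cap) in enumerate(regions):
            size = int(cap.sum())
            if size == 0:
                continue
            overlap = int((mask[window] & cap).sum())
            if rule.min_overlap_fraction is None:
                flags[k] = overlap >= 1
            else:
                flags[k] = overlap / size >= rule.min_overlap_fraction
        table[ch] = flags
    return table


def positive_fraction(cells: pd.DataFrame, marker: str) -> float:
    """Fraction of all cells positive for ``marker`` (nuclei define the denominator)."""
    if len(cells) == 0:
        raise ValueError("cannot compute a positive fraction over zero cells")
    if marker not in cells.columns:
        raise KeyError(f"marker column {marker!r} not present on the cell table")
    return float(cells[marker].astype(bool).mean())
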