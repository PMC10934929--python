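"""Hyperspectral cubes, per-egg ROI masks, and mean-spectrum extraction.

A transmission frame nominally holds four eggs.  The ROI of each egg is
segmented once on a single high-contrast band (band 38, ~1078 nm under the
linear axis convention) and the resulting mask is punched through all bands
unchanged; the mean spectrum of an egg is the per-band arithmetic mean over
its masked pixels.

Band indices are 1-based throughout, matching the instrument convention; the
wavelength axis is linear with inclusive endpoints (default 900–1700 nm).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops

from .metrics import LABELS

log = logging.getLogger(__name__)

WAVELENGTH_LO_NM = 900.0
WAVELENGTH_HI_NM = 1700.0
SEGMENTATION_BAND = 38          # highest egg/background contrast band
DEFAULT_MAX_EGGS = 4
MIN_AREA_FRACTION = 0.005       # default min component area: 0.5% of frame

#: recorded in output metadata so downstream files are self-describing
WAVELENGTH_CONVENTION = "linear, inclusive endpoints, 1-based band index"


def band_wavelength(band_index: int, n_bands: int,
                    lo_nm: float = WAVELENGTH_LO_NM,
                    hi_nm: float = WAVELENGTH_HI_NM) -> float:
    """Wavelength (nm) of a 1-based band on the linear inclusive axis."""
    if not 1 <= band_index <= n_bands:
        raise IndexError(f"band_index {band_index} outside 1..{n_bands}")
    if not lo_nm < hi_nm:
        raise ValueError(f"need lo < hi, got {lo_nm} >= {hi_nm}")
    return lo_nm + (band_index - 1) * (hi_nm - lo_nm) / (n_bands - 1)


def default_wavelength_axis(n_bands: int, lo_nm: float = WAVELENGTH_LO_NM,
                            hi_nm: float = WAVELENGTH_HI_NM) -> np.ndarray:
    return np.linspace(lo_nm, hi_nm, n_bands)


@dataclass
class Hypercube:
    """3-D intensity array (rows x cols x bands) with a nm wavelength axis."""

    data: np.ndarray
    wavelengths: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube contains non-finite intensities")
        if np.min(self.data) < 0:
            raise ValueError("cube contains negative intensities")
        if self.wavelengths.shape[0] != self.data.shape[2]:
            raise ValueError(f"{self.wavelengths.shape[0]} wavelengths for "
                             f"{self.data.shape[2]} bands")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band(self, band_index: int) -> np.ndarray:
        """Single-band slice (1-based index)."""
        if not 1 <= band_index <= self.n_bands:
            raise IndexError(f"band {band_index} outside 1..{self.n_bands}")
        return self.data[:, :, band_index - 1]


@dataclass
class EggMask:
    """Boolean ROI of one egg within a frame."""

    grid: np.ndarray
    egg_id: str
    pixel_count: int = 0

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2-D")
        count = int(self.grid.sum())
        if self.pixel_count == 0:
            self.pixel_count = count
        elif self.pixel_count != count:
            raise ValueError(f"pixel_count {self.pixel_count} != {count} true cells")
        if self.pixel_count == 0:
            raise ValueError("mask is empty")

    def to_rle(self) -> pd.DataFrame:
        """Run-length rows (egg_id, row, col_start, col_end), end inclusive."""
        rows = []
        for r in range(self.grid.shape[0]):
            line = self.grid[r]
            padded = np.diff(np.concatenate([[0], line.astype(int), [0]]))
            for start, end in zip(np.flatnonzero(padded == 1),
                                  np.flatnonzero(padded == -1) - 1):
                rows.append({"egg_id": self.egg_id, "row": r,
                             "col_start": int(start), "col_end": int(end)})
        return pd.DataFrame(rows)

    def to_png(self, path) -> None:
        import imageio.v3 as iio
        iio.imwrite(path, (self.grid.astype(np.uint8) * 255))


def segment_eggs(cube: Hypercube, band_index: int = SEGMENTATION_BAND,
                 min_area: Optional[int] = None,
                 max_eggs: int = DEFAULT_MAX_EGGS) -> list[EggMask]:
    """Segment egg ROIs on one band: Otsu threshold, 4-connected components.

    Components below ``min_area`` (default 0.5% of the frame) are dropped;
    the ``max_eggs`` largest survive, ordered by decreasing area with
    row-major top-left position breaking ties.  A frame with no usable
    contrast yields an empty list and a warning.
    """
    sl = cube.band(band_index)
    if min_area is None:
        min_area = max(1, int(round(MIN_AREA_FRACTION * sl.size)))
    if min_area < 1:
        raise ValueError(f"min_area must be >= 1, got {min_area}")
    if max_eggs < 1:
        raise ValueError(f"max_eggs must be >= 1, got {max_eggs}")

    if np.ptp(sl) == 0:
        warnings.warn("blank frame: no contrast at segmentation band", stacklevel=2)
        return []
    fg = sl > threshold_otsu(sl)
    labelled = cc_label(fg, connectivity=1)
    regions = [r for r in regionprops(labelled) if r.area >= min_area]
    if not regions:
        warnings.warn("blank frame: no component above min_area", stacklevel=2)
        return []

    def topleft(region):
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        order = np.lexsort((cc, rr))
        return int(rr[order[0]]) * sl.shape[1] + int(cc[order[0]])

    regions.sort(key=lambda r: (-r.area, topleft(r)))
    masks = []
    for k, region in enumerate(regions[:max_eggs], start=1):
        masks.append(EggMask(grid=labelled == region.label, egg_id=f"egg-{k}"))
    return masks


def mean_spectrum(cube: Hypercube, mask: EggMask) -> np.ndarray:
    """Per-band arithmetic mean over the masked pixels."""
    if mask.grid.shape != cube.data.shape[:2]:
        raise ValueError(f"mask shape {mask.grid.shape} != frame shape "
                         f"{cube.data.shape[:2]}")
    if mask.pixel_count < 1:
        raise ValueError("mask covers no pixels")
    return cube.data[mask.grid].mean(axis=0)


@dataclass
class SpectrumSet:
    """Mean spectra for a set of eggs on one incubation day.

    X is (n eggs, p bands); y holds labels from {fertile, non-fertile}.
    """

    X: np.ndarray
    y: np.ndarray
    day: int
    ids: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=object)
        self.ids = np.asarray(self.ids, dtype=object)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        n, p = self.X.shape
        if n < 2:
            raise ValueError(f"need at least 2 spectra, got {n}")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("spectra contain non-finite values")
        if self.y.shape[0] != n or self.ids.shape[0] != n:
            raise ValueError("labels/ids length mismatch with X rows")
        if self.wavelengths.shape[0] != p:
            raise ValueError("wavelength axis length mismatch with X columns")
        bad = set(map(str, self.y)) - LABELS
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)!r}")
        if not 0 <= int(self.day) <= 4:
            raise ValueError(f"day must be 0..4, got {self.day}")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def class_counts(self) -> dict:
        vals, counts = np.unique(self.y.astype(str), return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def subset(self, idx) -> "SpectrumSet":
        idx = np.asarray(idx)
        return SpectrumSet(X=self.X[idx], y=self.y[idx], day=self.day,
                           ids=self.ids[idx], wavelengths=self.wavelengths)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{w:.4f}" for w in self.wavelengths]
        df = pd.DataFrame(self.X, columns=cols)
        df.insert(0, "label", self.y)
        df.insert(0, "day", int(self.day))
        df.insert(0, "egg_id", self.ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectrumSet":
        df = pd.read_csv(path, comment="#")
        meta_cols = ["egg_id", "day", "label"]
        missing = [c for c in meta_cols if c not in df.columns]
        if missing:
            raise ValueError(f"spectra CSV missing column(s) {missing}")
        band_cols = [c for c in df.columns if c not in meta_cols]
        days = df["day"].unique()
        if len(days) != 1:
            raise ValueError(f"spectra CSV mixes days {sorted(days)}; one day per set")
        return cls(X=df[band_cols].to_numpy(float),
                   y=df["label"].to_numpy(object),
                   day=int(days[0]),
                   ids=df["egg_id"].to_numpy(object),
                   wavelengths=np.array([float(c) for c in band_cols]))


def extract_spectra(cube: Hypercube, masks: Sequence[EggMask], day: int,
                    labels: Optional[Sequence[str]] = None) -> SpectrumSet:
    """Mean spectrum per mask, assembled into a SpectrumSet.

    ``labels`` defaults to whatever ``cube.meta['egg_classes']`` records (the
    synthetic generator writes it); otherwise labels must be supplied.
    """
    if labels is None:
        labels = cube.meta.get("egg_classes")
    if labels is None or len(labels) != len(masks):
        raise ValueError("need one fertility label per mask")
    X = np.vstack([mean_spectrum(cube, m) for m in masks])
    return SpectrumSet(X=X, y=np.asarray(labels, dtype=object), day=day,
                       ids=np.array([m.egg_id for m in masks], dtype=object),
                       wavelengths=cube.wavelengths)
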