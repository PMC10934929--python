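"""Seeded generator of egg-like NIR transmittance spectra and toy frames.

No imaging data were deposited with the study this emulates, so the package
ships a generative stand-in with the statistical structure the analysis
assumes: each mean spectrum is a smooth baseline plus one dominant Gaussian
transmittance peak centred at the segmentation band (~1078 nm), with

* class-dependent peak amplitude — non-fertile eggs transmit more, the gap
  controlled by a single ``separation`` parameter (δ);
* day-dependent attenuation — the fertile peak amplitude is non-increasing
  over incubation days 0–3 as the developing embryo absorbs more light,
  while the non-fertile day profile may be non-monotone;
* smooth, finite-rank within-class spectral variation, truncated at zero
  (intensities are non-negative);
* the study's class imbalance (312 fertile : 23 non-fertile on day 0).

The noise model deserves a word.  A mean spectrum averages ~10^3 ROI pixels,
so per-band sensor noise is averaged away; what remains is egg-to-egg
variation (shell thickness, pigmentation, albumen volume), which is spectrally
smooth.  Each spectrum's deviation is therefore a random combination of
``noise_modes`` broad Gaussian modes spanning the axis, scaled so every band
has marginal standard deviation ``noise_sd``.  The deviation field has exact
rank ``noise_modes``.

δ = 0 is an exact null: both classes are then drawn from the same
distribution.  All outputs are bit-reproducible from the config seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import yaml

from .hypercube import (Hypercube, SpectrumSet, band_wavelength,
                        default_wavelength_axis)
from .metrics import FERTILE, NONFERTILE


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic transmittance model.

    Amplitudes are in the same arbitrary intensity units as the baseline.
    The effective non-fertile peak amplitude on day d is
    ``fertile_amp[d] + separation * nonfertile_profile[d]``: the day shape of
    the extra non-fertile transmittance is configurable, but δ = 0 always
    collapses the two classes onto one distribution.
    """

    n_fertile: int = 312
    n_nonfertile: int = 23
    n_bands: int = 167
    wavelength_lo: float = 900.0
    wavelength_hi: float = 1700.0
    peak_band: int = 38             # 1-based; ~1078 nm on the default axis
    peak_width: float = 12.0        # Gaussian sigma, in bands
    fertile_amp: tuple = (1.00, 0.90, 0.80, 0.72, 0.65)
    nonfertile_profile: tuple = (1.00, 0.85, 1.05, 1.00, 0.90)
    separation: float = 0.20        # class mean-amplitude gap δ
    noise_sd: float = 0.02          # per-band sd of within-class variation
    noise_modes: int = 8            # rank of the smooth deviation field
    baseline_level: float = 0.20    # additive smooth profile: level + tilt * u
    baseline_tilt: float = -0.08    # u runs 0..1 across the axis
    day: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_fertile < 1 or self.n_nonfertile < 1:
            raise ValueError("class counts must be >= 1")
        if self.n_bands < 2:
            raise ValueError("need at least 2 bands")
        if not 1 <= self.peak_band <= self.n_bands:
            raise ValueError(f"peak_band {self.peak_band} outside 1..{self.n_bands}")
        if self.noise_sd < 0 or self.separation < 0:
            raise ValueError("noise_sd and separation must be >= 0")
        if self.noise_modes < 1:
            raise ValueError("noise_modes must be >= 1")
        if not 0 <= self.day <= 4:
            raise ValueError(f"day must be 0..4, got {self.day}")
        fa = tuple(float(v) for v in self.fertile_amp)
        if len(fa) != 5 or len(self.nonfertile_profile) != 5:
            raise ValueError("amplitude profiles must cover days 0..4")
        if any(b > a for a, b in zip(fa[:3], fa[1:4])):
            # embryonic absorption only grows through day 3
            raise ValueError("fertile_amp must be non-increasing over days 0-3")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_file(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = fh.read()
        doc = json.loads(raw) if str(path).endswith(".json") else yaml.safe_load(raw)
        for key in ("fertile_amp", "nonfertile_profile"):
            if key in doc and isinstance(doc[key], list):
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    def with_(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)

    # -- model internals ---------------------------------------------------
    def wavelengths(self) -> np.ndarray:
        return default_wavelength_axis(self.n_bands, self.wavelength_lo,
                                       self.wavelength_hi)

    def peak_amplitude(self, label: str, day: Optional[int] = None) -> float:
        d = self.day if day is None else day
        amp = float(self.fertile_amp[d])
        if label == NONFERTILE:
            amp += self.separation * float(self.nonfertile_profile[d])
        return amp

    def template(self, label: str, day: Optional[int] = None) -> np.ndarray:
        """Noise-free class mean spectrum."""
        lam = self.wavelengths()
        u = (lam - self.wavelength_lo) / (self.wavelength_hi - self.wavelength_lo)
        baseline = self.baseline_level + self.baseline_tilt * u
        center = band_wavelength(self.peak_band, self.n_bands,
                                 self.wavelength_lo, self.wavelength_hi)
        step = (self.wavelength_hi - self.wavelength_lo) / (self.n_bands - 1)
        sigma = self.peak_width * step
        peak = np.exp(-0.5 * ((lam - center) / sigma) ** 2)
        return np.maximum(baseline + self.peak_amplitude(label, day) * peak, 0.0)

    def noise_basis(self) -> np.ndarray:
        """(noise_modes, n_bands) smooth basis, columns scaled to unit sd."""
        lam = self.wavelengths()
        centers = np.linspace(self.wavelength_lo, self.wavelength_hi,
                              self.noise_modes)
        sigma = (self.wavelength_hi - self.wavelength_lo) / self.noise_modes
        phi = np.exp(-0.5 * ((lam[None, :] - centers[:, None]) / sigma) ** 2)
        return phi / np.sqrt((phi ** 2).sum(axis=0))

    def draw_noise(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """(n, n_bands) smooth deviations, per-band marginal sd = noise_sd."""
        if self.noise_sd == 0:
            return np.zeros((n, self.n_bands))
        coeff = rng.normal(0.0, 1.0, size=(n, self.noise_modes))
        return self.noise_sd * (coeff @ self.noise_basis())


def generate_spectra(config: GeneratorConfig) -> SpectrumSet:
    """Draw one SpectrumSet (fertile block first, then non-fertile)."""
    rng = np.random.default_rng(config.seed)
    counts = [(FERTILE, config.n_fertile), (NONFERTILE, config.n_nonfertile)]
    blocks, labels, ids = [], [], []
    k = 0
    for label, n in counts:
        tmpl = config.template(label)
        blocks.append(np.maximum(tmpl + config.draw_noise(rng, n), 0.0))
        labels += [label] * n
        ids += [f"egg-{i:04d}" for i in range(k, k + n)]
        k += n
    return SpectrumSet(X=np.vstack(blocks), y=np.array(labels, dtype=object),
                       day=config.day, ids=np.array(ids, dtype=object),
                       wavelengths=config.wavelengths())


@dataclass
class SyntheticFrameSpec:
    """Geometry of a toy four-egg transmission frame."""

    rows: int = 96
    cols: int = 160
    egg_centers: tuple = ((26, 40), (26, 120), (70, 40), (70, 120))
    egg_axes: tuple = (16, 22)      # ellipse semi-axes (row, col), pixels
    background_level: float = 0.02
    egg_classes: tuple = (FERTILE, FERTILE, FERTILE, NONFERTILE)

    def footprints(self) -> list[np.ndarray]:
        rr, cc = np.mgrid[0:self.rows, 0:self.cols]
        ar, ac = self.egg_axes
        masks = []
        for (r0, c0) in self.egg_centers:
            if not (ar <= r0 <= self.rows - 1 - ar and ac <= c0 <= self.cols - 1 - ac):
                raise ValueError(f"ellipse at ({r0},{c0}) does not fit the frame")
            masks.append(((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2 <= 1.0)
        total = np.zeros((self.rows, self.cols), dtype=int)
        for m in masks:
            total += m
        if np.any(total > 1):
            raise ValueError("egg ellipses overlap")
        return masks


def generate_hypercube(config: GeneratorConfig,
                       frame: Optional[SyntheticFrameSpec] = None) -> Hypercube:
    """Toy frame: background plus per-pixel class spectra inside each ellipse.

    The egg -> class assignment is recorded in ``meta['egg_classes']`` so the
    segmentation pipeline can be scored against the known truth.
    """
    frame = frame or SyntheticFrameSpec()
    rng = np.random.default_rng(config.seed)
    footprints = frame.footprints()
    data = np.full((frame.rows, frame.cols, config.n_bands),
                   frame.background_level, dtype=float)
    for mask, label in zip(footprints, frame.egg_classes):
        tmpl = config.template(label)
        data[mask] = np.maximum(tmpl + config.draw_noise(rng, int(mask.sum())), 0.0)
    meta = {
        "egg_classes": list(frame.egg_classes),
        "egg_footprints": [np.flatnonzero(m.ravel()).tolist() for m in footprints],
        "day": config.day,
        "seed": config.seed,
        "config_hash": config.config_hash(),
    }
    return Hypercube(data=data, wavelengths=config.wavelengths(), meta=meta)
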