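"""Leaf-tissue segmentation from the red-edge spectral slope.

Vegetation reflectance rises steeply between roughly 680 and 720 nm (the red
edge) while background materials stay spectrally flat.  Each pixel's spectrum
is sampled at equally spaced wavelengths across that window and dotted with a
zero-sum integer ramp kernel (-20..20 by default); the resulting score is
proportional to the red-edge slope and is zero for flat spectra.  Pixels
scoring above a fixed threshold (default 7, in reflectance-times-index units
on calibrated cubes) are leaf tissue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cube import SpectralCube, band_index

__all__ = ["SegmentationConfig", "LeafMask", "red_edge_score", "segment_leaf"]


@dataclass
class SegmentationConfig:
    kernel: np.ndarray = field(default_factory=lambda: np.arange(-20, 21, dtype=np.float64))
    red_edge_window: tuple[float, float] = (680.0, 720.0)
    threshold: float = 7.0
    resample_points: int | None = None  # defaults to kernel length
    sampling: str = "interpolate"  # or "nearest_bands"

    def __post_init__(self) -> None:
        self.kernel = np.asarray(self.kernel, dtype=np.float64).ravel()
        if self.resample_points is None:
            self.resample_points = self.kernel.size
        if self.resample_points != self.kernel.size:
            raise ValueError(
                f"kernel length {self.kernel.size} != resample_points {self.resample_points}"
            )
        lo, hi = self.red_edge_window
        if not lo < hi:
            raise ValueError("red_edge_window must satisfy lo < hi")
        if self.sampling not in ("interpolate", "nearest_bands"):
            raise ValueError(f"unknown sampling mode {self.sampling!r}")


@dataclass
class LeafMask:
    """Boolean foreground map over (y, x)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def n_foreground(self) -> int:
        return int(self.values.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_png(self, path: str | Path) -> None:
        from PIL import Image

        Image.fromarray((self.values * np.uint8(255))).save(Path(path))

    def to_rle_json(self, path: str | Path | None = None) -> str:
        """Row-major run-length encoding of the foreground, as JSON."""
        flat = self.values.ravel()
        starts, lengths = _true_runs(flat)
        payload = json.dumps(
            {"shape": list(self.values.shape),
             "runs": [[int(s), int(l)] for s, l in zip(starts, lengths)]}
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_rle_json(cls, payload: str) -> "LeafMask":
        obj = json.loads(payload)
        flat = np.zeros(int(np.prod(obj["shape"])), dtype=bool)
        for start, length in obj["runs"]:
            flat[start:start + length] = True
        return cls(flat.reshape(obj["shape"]))


def _true_runs(flat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    padded = np.concatenate([[False], flat, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[::2], edges[1::2]
    return starts, stops - starts


def _band_weights(cube: SpectralCube, cfg: SegmentationConfig) -> np.ndarray:
    """Collapse kernel x resampling into one weight per band.

    The score is linear in the spectrum, so interpolating at the sample
    wavelengths and dotting with the kernel equals a single dot product with
    per-band accumulated weights.
    """
    lo, hi = cfg.red_edge_window
    w = cube.wavelengths
    if lo < w[0] or hi > w[-1]:
        raise ValueError(
            f"red-edge window [{lo:g}, {hi:g}] nm outside cube wavelength "
            f"range [{w[0]:g}, {w[-1]:g}] nm"
        )
    samples = np.linspace(lo, hi, cfg.resample_points)
    weights = np.zeros(w.size, dtype=np.float64)
    if cfg.sampling == "nearest_bands":
        for k, lam in zip(cfg.kernel, samples):
            weights[band_index(cube, lam)] += k
        return weights
    for k, lam in zip(cfg.kernel, samples):
        j = int(np.searchsorted(w, lam))
        if j == 0:
            weights[0] += k
        elif j >= w.size:
            weights[-1] += k
        elif w[j] == lam:
            weights[j] += k
        else:
            t = (lam - w[j - 1]) / (w[j] - w[j - 1])
            weights[j - 1] += k * (1.0 - t)
            weights[j] += k * t
    return weights


def red_edge_score(cube: SpectralCube, cfg: SegmentationConfig | None = None) -> np.ndarray:
    """Per-pixel red-edge slope score (dot of resampled spectrum with kernel)."""
    cfg = cfg if cfg is not None else SegmentationConfig()
    weights = _band_weights(cube, cfg)
    return cube.values.astype(np.float64) @ weights


def segment_leaf(
    cube: SpectralCube,
    cfg: SegmentationConfig | None = None,
    largest_component: bool = False,
) -> LeafMask:
    """Threshold the red-edge score into a leaf mask (score > threshold).

    ``largest_component=True`` keeps only the largest 8-connected foreground
    component (off by default: no morphological post-processing).
    """
    cfg = cfg if cfg is not None else SegmentationConfig()
    mask = red_edge_score(cube, cfg) > cfg.threshold
    if largest_component and mask.any():
        from scipy import ndimage

        labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
        if n > 1:
            counts = np.bincount(labels.ravel())
            counts[0] = 0
            mask = labels == int(np.argmax(counts))
    return LeafMask(mask)
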