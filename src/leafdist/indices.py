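"""Per-pixel vegetation-index maps and whole-leaf averages.

NDVI is computed per leaf pixel as (R_800 - R_650) / (R_800 + R_650), using
the bands nearest 800 and 650 nm.  Pixels whose denominator is not positive
are marked invalid rather than clipped, so they never bias the whole-leaf
average.  Heatmaps use the jet colormap on a fixed 0..1 scale (blue = 0,
red = 1) so images are comparable across leaves and treatments.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cube import SpectralCube, band_index
from .segment import LeafMask

__all__ = ["VIMap", "ndvi_map", "two_band_index_map", "averaged_index", "heatmap_png"]

NDVI_NIR_NM = 800.0
NDVI_RED_NM = 650.0


@dataclass
class VIMap:
    """Per-pixel index image with a validity mask (NaN where invalid)."""

    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape or self.values.ndim != 2:
            raise ValueError("VIMap values and valid mask must be matching 2-D arrays")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_csv(self, path: str | Path) -> None:
        grid = np.where(self.valid, self.values, np.nan)
        np.savetxt(Path(path), grid, delimiter=",", fmt="%.9g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "VIMap":
        grid = np.atleast_2d(np.genfromtxt(Path(path), delimiter=","))
        return cls(grid, np.isfinite(grid))


def two_band_index_map(
    cube: SpectralCube, mask: LeafMask, nir_nm: float, red_nm: float
) -> VIMap:
    """Generic normalized-difference map (R_nir - R_red)/(R_nir + R_red)."""
    if not cube.calibrated:
        raise ValueError("vegetation indices require a calibrated cube")
    if mask.shape != (cube.n_rows, cube.n_cols):
        raise ValueError(
            f"mask shape {mask.shape} incompatible with cube spatial shape "
            f"({cube.n_rows}, {cube.n_cols})"
        )
    nir = cube.values[:, :, band_index(cube, nir_nm)].astype(np.float64)
    red = cube.values[:, :, band_index(cube, red_nm)].astype(np.float64)
    den = nir + red
    valid = mask.values & (den > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(valid, (nir - red) / np.where(valid, den, 1.0), np.nan)
    return VIMap(values, valid)


def ndvi_map(cube: SpectralCube, mask: LeafMask) -> VIMap:
    """NDVI per leaf pixel from the bands nearest 800 nm (NIR) and 650 nm (red)."""
    return two_band_index_map(cube, mask, NDVI_NIR_NM, NDVI_RED_NM)


def averaged_index(vi: VIMap) -> float:
    """Arithmetic mean of the index over valid pixels (the whole-leaf value)."""
    if not vi.valid.any():
        raise ValueError("no leaf pixels: cannot average an empty index map")
    return float(vi.values[vi.valid].mean())


def heatmap_png(vi: VIMap, path: str | Path) -> None:
    """Write a jet-colormap PNG on a fixed [0, 1] scale; invalid pixels black."""
    import matplotlib

    from PIL import Image

    cmap = matplotlib.colormaps["jet"]
    scaled = np.clip(np.where(vi.valid, vi.values, 0.0), 0.0, 1.0)
    rgba = cmap(scaled, bytes=True)
    rgb = rgba[:, :, :3].copy()
    rgb[~vi.valid] = 0
    Image.fromarray(rgb).save(Path(path))
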