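"""Synthetic push-broom hyperspectral leaf scenes with known ground truth.

No field imagery ships with this package, so cohorts for testing and for the
statistical harness are simulated.  A scene emulates a line-scanned corn
leaf: an elliptical mask tapering from collar to tip on a dark flat
background, leaf spectra built from a flat red level, a flat NIR level and a
linear red-edge ramp (680-720 nm), and dark/white reference frames from
which a raw-DN cube is synthesised so the full calibration path is
exercised.

Each leaf's per-column NDVI target follows a treatment-specific template:
rising from the collar to a plateau, then dropping sharply past 90 % of the
length.  High-N leaves sit at a higher level with a shallower rise and
smaller tip drop than low-N leaves.  Templates are calibrated (with
elliptical-chord weights, since whole-leaf averages are pixel means) so the
default whole-leaf NDVI means are 0.845 (high N) and 0.837 (low N) with a
between-leaf level SD of 0.006 — the magnitudes typical of nitrogen trials
at this growth stage.  Between-leaf shape jitter and within-leaf reflectance
noise are separate knobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

from .cube import ReferenceSet, SpectralCube
from .segment import LeafMask

__all__ = [
    "LeafSimParams",
    "SimulatedLeaf",
    "SimulatedCohort",
    "default_template",
    "generate_leaf",
    "iter_cohort",
    "generate_cohort",
    "preset",
]

TREATMENTS = ("high", "low", "efficient")


@dataclass
class LeafSimParams:
    """Geometry, spectral layout, and statistical structure of simulated leaves."""

    leaf_length_columns: int = 254
    width_rows: int = 878
    n_bands: int = 676
    wavelength_range: tuple[float, float] = (450.0, 900.0)
    # whole-leaf (pixel-mean) NDVI targets per treatment arm
    treatment_mean: dict = field(
        default_factory=lambda: {"high": 0.845, "low": 0.837, "efficient": 0.848}
    )
    # between-leaf SD of the overall NDVI level, per arm
    level_sd: dict = field(
        default_factory=lambda: {"high": 0.006, "low": 0.006, "efficient": 0.008}
    )
    # template shape: collar rise amplitude/scale and quadratic tip drop
    rise_amplitude: dict = field(
        default_factory=lambda: {"high": 0.03, "low": 0.05, "efficient": 0.03}
    )
    rise_scale: dict = field(
        default_factory=lambda: {"high": 0.30, "low": 0.15, "efficient": 0.30}
    )
    tip_drop: dict = field(
        default_factory=lambda: {"high": 0.12, "low": 0.18, "efficient": 0.08}
    )
    tip_start: float = 0.9
    # between-leaf relative jitter on rise amplitude and tip drop
    shape_jitter_sd: float = 0.2
    # within-leaf per-band reflectance noise SD
    pixel_noise_sd: float = 0.01
    nir_reflectance: float = 0.5
    background_reflectance: float = 0.05
    white_level: float = 0.9
    dark_level: float = 0.05
    edge_margin_rows: int = 4

    def __post_init__(self) -> None:
        if min(self.leaf_length_columns, self.width_rows, self.n_bands) <= 0:
            raise ValueError("leaf dimensions must be positive")


def preset(name: str) -> LeafSimParams:
    """Named geometry presets; statistical structure is identical across them.

    - ``paperlike``: full acquisition geometry (254 x 878 pixels, 676 bands).
    - ``reduced``: 64-column leaves, full 878-pixel scan line, 100 bands.
    - ``fast``: small scenes (80 x 48, 60 bands) for replicated statistics.
    """
    base = LeafSimParams()
    if name == "paperlike":
        return base
    if name == "reduced":
        return replace(base, leaf_length_columns=64, n_bands=100)
    if name == "fast":
        return replace(base, leaf_length_columns=80, width_rows=48, n_bands=60)
    raise ValueError(f"unknown preset {name!r} (expected paperlike, reduced or fast)")


def _shape(u: np.ndarray, amplitude: float, scale: float, drop: float, tip_start: float) -> np.ndarray:
    tip = np.clip((u - tip_start) / (1.0 - tip_start), 0.0, None) ** 2
    return -amplitude * np.exp(-u / scale) - drop * tip


def _ellipse_weights(u: np.ndarray) -> np.ndarray:
    # chord length of the elliptical mask at relative position u: pixel count per column
    return np.sqrt(np.clip(1.0 - u**2, 0.0, None))


def default_template(
    treatment: str,
    u,
    params: LeafSimParams | None = None,
    amplitude_scale: float = 1.0,
    drop_scale: float = 1.0,
) -> np.ndarray:
    """Target NDVI at relative mid-rib position ``u`` in [0, 1].

    The shape term is centred with elliptical-chord weights so that the
    whole-leaf *pixel* mean of a noise-free leaf equals the treatment's
    target mean.  ``amplitude_scale``/``drop_scale`` apply per-leaf shape
    jitter without disturbing that calibration.
    """
    params = params if params is not None else LeafSimParams()
    if treatment not in TREATMENTS:
        raise ValueError(f"unknown treatment {treatment!r}; expected one of {TREATMENTS}")
    u = np.asarray(u, dtype=np.float64)
    if np.any((u < 0) | (u > 1)):
        raise ValueError("relative position u must lie in [0, 1]")
    a = params.rise_amplitude[treatment] * amplitude_scale
    s = params.rise_scale[treatment]
    d = params.tip_drop[treatment] * drop_scale
    fine = np.linspace(0.0, 1.0, 4001)
    offset = np.average(_shape(fine, a, s, d, params.tip_start), weights=_ellipse_weights(fine))
    out = params.treatment_mean[treatment] + _shape(u, a, s, d, params.tip_start) - offset
    if np.any(np.abs(out) >= 1):
        raise ValueError("infeasible NDVI target (|target| >= 1)")
    return out


@dataclass
class SimulatedLeaf:
    """One synthetic scene: raw cube, references, and ground truth."""

    raw: SpectralCube
    references: ReferenceSet
    mask: LeafMask
    treatment: str
    level_offset: float
    amplitude_scale: float
    drop_scale: float
    params: LeafSimParams

    def truth_template(self, u) -> np.ndarray:
        """Intended noise-free NDVI at relative position(s) u."""
        return (
            default_template(self.treatment, u, self.params,
                             self.amplitude_scale, self.drop_scale)
            + self.level_offset
        )

    def truth_profile(self, K: int = 50) -> np.ndarray:
        """Template values at the K section midpoints."""
        mid = (np.arange(K) + 0.5) / K
        return self.truth_template(mid)


def generate_leaf(
    params: LeafSimParams,
    treatment: str,
    rng: np.random.Generator,
) -> SimulatedLeaf:
    """Synthesize one raw scene plus its references and ground-truth mask.

    Leaf pixels receive a two-segment spectrum (flat red below 680 nm, flat
    NIR above 720 nm, linear ramp between) whose 650/800 nm levels realise
    the column's target NDVI; the ramp makes the red-edge segmentation score
    far exceed the threshold.  Background pixels are spectrally flat (score
    exactly 0).  The emitted cube is raw DN: reflectance folded through the
    white/dark references, so calibration recovers the reflectance exactly.
    """
    H, L, B = params.width_rows, params.leaf_length_columns, params.n_bands
    wav = np.linspace(*params.wavelength_range, B)

    amplitude_scale = float(np.clip(1.0 + rng.normal(0.0, params.shape_jitter_sd), 0.2, None))
    drop_scale = float(np.clip(1.0 + rng.normal(0.0, params.shape_jitter_sd), 0.2, None))
    level_offset = float(rng.normal(0.0, params.level_sd[treatment]))

    u = (np.arange(L) + 0.5) / L
    target = (
        default_template(treatment, u, params, amplitude_scale, drop_scale) + level_offset
    )
    if np.any(np.abs(target) >= 1):
        raise ValueError("infeasible NDVI target (|target| >= 1)")

    # elliptical mask tapering to the tip; every column keeps >= 1 pixel
    yc = (H - 1) / 2.0
    half_width = np.maximum(
        (H / 2.0 - params.edge_margin_rows) * _ellipse_weights(u), 0.6
    )
    rows = np.arange(H)
    mask = np.abs(rows[:, None] - yc) <= half_width[None, :]

    # spectra: NDVI target -> red level, given fixed NIR level
    nir = params.nir_reflectance
    red_col = nir * (1.0 - target) / (1.0 + target)
    ramp = np.clip((wav - 680.0) / 40.0, 0.0, 1.0)
    reflectance = np.full((H, L, B), params.background_reflectance, dtype=np.float64)
    red_pix = np.broadcast_to(red_col[None, :], (H, L))[mask]
    reflectance[mask] = red_pix[:, None] + (nir - red_pix[:, None]) * ramp[None, :]
    if params.pixel_noise_sd > 0:
        noise = rng.normal(0.0, params.pixel_noise_sd, size=(int(mask.sum()), B))
        reflectance[mask] = np.clip(reflectance[mask] + noise, 1e-4, None)

    # references per sensor-line pixel, with mild row/band structure
    white = (
        params.white_level
        * (1.0 + 0.02 * np.sin(np.linspace(0.0, 3.0 * np.pi, H)))[:, None]
        * (1.0 + 0.03 * np.linspace(-1.0, 1.0, B))[None, :]
    )
    dark = np.full((H, B), params.dark_level)
    raw_values = reflectance * (white + dark)[:, None, :] + dark[:, None, :]

    raw = SpectralCube(
        raw_values,
        wav,
        meta={"treatment": treatment, "simulated": "1"},
        calibrated=False,
    )
    return SimulatedLeaf(
        raw=raw,
        references=ReferenceSet(dark=dark, white=white),
        mask=LeafMask(mask),
        treatment=treatment,
        level_offset=level_offset,
        amplitude_scale=amplitude_scale,
        drop_scale=drop_scale,
        params=params,
    )


def _arm_plan(n_per_group: int, n_efficient: int) -> list[tuple[str, str, int]]:
    plan = [("high", "control", 1)] * n_per_group + [("low", "control", 0)] * n_per_group
    plan += [("efficient", "efficient", 1)] * n_efficient
    return plan


def iter_cohort(
    n_per_group: int,
    params: LeafSimParams | None = None,
    seed: int = 0,
    n_efficient: int = 0,
) -> Iterator[tuple[dict, SimulatedLeaf]]:
    """Yield (manifest row, leaf) pairs one at a time (cubes can be large)."""
    if n_per_group < 2:
        raise ValueError("n_per_group must be at least 2")
    params = params if params is not None else LeafSimParams()
    rng = np.random.default_rng(seed)
    for i, (treatment, genotype, label) in enumerate(_arm_plan(n_per_group, n_efficient)):
        leaf = generate_leaf(params, treatment, rng)
        row = {
            "id": f"leaf{i:03d}",
            "genotype": genotype,
            "treatment": treatment,
            "label": label,
            "seed": seed,
        }
        yield row, leaf


@dataclass
class SimulatedCohort:
    leaves: list
    manifest: pd.DataFrame

    @property
    def labels(self) -> np.ndarray:
        return self.manifest["label"].to_numpy(int)


def generate_cohort(
    n_per_group: int,
    params: LeafSimParams | None = None,
    seed: int = 0,
    n_efficient: int = 0,
) -> SimulatedCohort:
    """Materialise a balanced cohort (n high-N + n low-N, optional genotype arm)."""
    rows, leaves = [], []
    for row, leaf in iter_cohort(n_per_group, params, seed, n_efficient):
        rows.append(row)
        leaves.append(leaf)
    return SimulatedCohort(leaves=leaves, manifest=pd.DataFrame(rows))
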