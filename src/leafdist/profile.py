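"""Mid-rib NDVI distribution profiles and cohort feature matrices.

A leaf's index map is reduced to a length-K feature vector in three steps:
(1) average valid pixels within each scan line (one value per mid-rib
column), (2) rescale the variable leaf length to a common axis, and
(3) average within K equal sections from collar to tip (default K = 50).

Rescaling treats the raw per-column profile as a piecewise-constant function
on [0, L) and takes exact length-weighted means over the K equal real-valued
intervals.  This reduces to plain block means when L is divisible by K and
preserves the profile mean in general.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .indices import VIMap

__all__ = [
    "DEFAULT_SECTIONS",
    "DistributionProfile",
    "CohortDataset",
    "line_means",
    "rescale_profile",
    "build_cohort",
]

DEFAULT_SECTIONS = 50


@dataclass
class DistributionProfile:
    """Length-K vector of section-mean index values, collar (0) to tip (K-1)."""

    values: np.ndarray
    K: int = DEFAULT_SECTIONS
    source_length: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.values.size != self.K:
            raise ValueError(f"profile has {self.values.size} sections, expected K={self.K}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile contains non-finite values")


@dataclass
class CohortDataset:
    """N x K feature matrix with binary treatment labels and row metadata."""

    features: np.ndarray
    labels: np.ndarray
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D (leaves x sections)")
        if self.labels.shape != (self.features.shape[0],):
            raise ValueError("labels must align with feature rows")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be binary 0/1")
        self.labels = self.labels.astype(int)
        if len(self.meta) not in (0, self.features.shape[0]):
            raise ValueError("metadata rows must align with feature rows")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def k(self) -> int:
        return self.features.shape[1]

    def to_csv(self, path: str | Path) -> None:
        df = self.meta.reset_index(drop=True).copy() if len(self.meta) else pd.DataFrame(index=range(self.n))
        df["label"] = self.labels
        width = max(2, len(str(self.k)))
        for j in range(self.k):
            df[f"s{j + 1:0{width}d}"] = self.features[:, j]
        df.to_csv(Path(path), index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortDataset":
        df = pd.read_csv(Path(path))
        section_cols = [c for c in df.columns if c.startswith("s") and c[1:].isdigit()]
        section_cols.sort(key=lambda c: int(c[1:]))
        if not section_cols:
            raise ValueError(f"no section columns (s01..sK) found in {path}")
        meta_cols = [c for c in df.columns if c not in section_cols and c != "label"]
        return cls(df[section_cols].to_numpy(float), df["label"].to_numpy(), df[meta_cols])


def line_means(vi: VIMap, max_empty_frac: float = 0.2) -> np.ndarray:
    """Mean valid index per mid-rib column, trimmed and hole-filled.

    Empty columns at either end of the leaf are trimmed.  Interior empty
    columns (segmentation holes) are filled by linear interpolation between
    their nonempty neighbours; if they exceed ``max_empty_frac`` of the
    leaf's extent the leaf is rejected as low quality.
    """
    counts = vi.valid.sum(axis=0)
    if not counts.any():
        raise ValueError("no leaf pixels: index map has no valid columns")
    nonempty = counts > 0
    first = int(np.argmax(nonempty))
    last = len(nonempty) - 1 - int(np.argmax(nonempty[::-1]))
    counts = counts[first:last + 1]
    sums = np.where(vi.valid, vi.values, 0.0).sum(axis=0)[first:last + 1]
    filled = counts > 0
    raw = np.full(counts.shape, np.nan)
    raw[filled] = sums[filled] / counts[filled]
    holes = ~filled
    if holes.any():
        frac = holes.mean()
        if frac > max_empty_frac:
            raise ValueError(
                f"leaf rejected: {frac:.0%} of columns between collar and tip are "
                f"empty (limit {max_empty_frac:.0%})"
            )
        idx = np.arange(raw.size)
        raw[holes] = np.interp(idx[holes], idx[filled], raw[filled])
    return raw


def rescale_profile(raw: Sequence[float] | np.ndarray, K: int = DEFAULT_SECTIONS) -> DistributionProfile:
    """Rescale a raw per-column profile of length L to K equal sections.

    The raw profile is read as a step function on [0, L); section j spans
    [jL/K, (j+1)L/K) and takes the length-weighted mean of the overlapping
    raw values (exact piecewise-constant integration via the cumulative sum).
    """
    raw = np.asarray(raw, dtype=np.float64).ravel()
    L = raw.size
    if L < 2:
        raise ValueError(f"raw profile of length {L} too short to rescale (need >= 2)")
    cumulative = np.concatenate([[0.0], np.cumsum(raw)])
    edges = np.linspace(0.0, float(L), K + 1)
    cum_at_edges = np.interp(edges, np.arange(L + 1, dtype=np.float64), cumulative)
    values = np.diff(cum_at_edges) / (L / K)
    return DistributionProfile(values, K=K, source_length=L)


def build_cohort(
    profiles: Sequence[DistributionProfile],
    labels: Sequence[int],
    metadata: pd.DataFrame | dict | None = None,
) -> CohortDataset:
    """Stack per-leaf profiles into an N x K design matrix with 0/1 labels."""
    if len(profiles) == 0:
        raise ValueError("empty cohort")
    if len(labels) != len(profiles):
        raise ValueError(f"{len(labels)} labels for {len(profiles)} profiles")
    K = profiles[0].K
    for i, p in enumerate(profiles):
        if p.K != K:
            raise ValueError(f"profile row {i} has K={p.K}, expected K={K}")
    features = np.vstack([p.values for p in profiles])
    meta = pd.DataFrame(metadata) if metadata is not None else pd.DataFrame()
    return CohortDataset(features, np.asarray(labels), meta)
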