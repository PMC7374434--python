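"""Hyperspectral cube container, ENVI-format I/O, and reflectance calibration.

The in-memory convention follows a push-broom line scanner: axis 0 (rows, Y)
is the across-leaf direction sampled by the sensor line, axis 1 (columns, X)
advances along the leaf mid-rib as the specimen slides through the imager
(column 0 at the leaf collar), and axis 2 is the spectral band axis with a
strictly increasing wavelength vector in nanometres.

Raw digital numbers are converted to reflectance against a white Teflon
reference strip and a dark-current frame.  The default correction is

    R_cali = (R_raw - R_dark) / (R_white + R_dark)

with the conventional flat-field denominator (R_white - R_dark) available as
an option.  References captured per sensor line are (row, band) frames that
broadcast along the scan direction; full reference cubes are averaged over
the scan direction first.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

__all__ = [
    "DEFAULT_SENSOR_RANGE",
    "SpectralCube",
    "ReferenceSet",
    "band_index",
    "calibrate",
    "read_envi_cube",
    "write_envi_cube",
]

DEFAULT_SENSOR_RANGE = (450.0, 900.0)

# ENVI "data type" codes <-> numpy dtypes (little-endian on disk by default)
_ENVI_TO_NUMPY = {
    1: "u1",
    2: "i2",
    3: "i4",
    4: "f4",
    5: "f8",
    12: "u2",
    13: "u4",
    14: "i8",
}
_NUMPY_TO_ENVI = {np.dtype(v): k for k, v in _ENVI_TO_NUMPY.items()}
_INTERLEAVES = ("bil", "bip", "bsq")


@dataclass
class SpectralCube:
    """A (row, column, band) reflectance or raw-DN block with a wavelength axis.

    Parameters
    ----------
    values
        3-D array indexed ``(y, x, band)``.
    wavelengths
        Band-centre wavelengths in nm, strictly increasing, one per band.
    meta
        Free-form provenance (device, exposure, calibration note, ...).
    calibrated
        True once the cube holds reflectance rather than raw counts;
        calibrated values must be finite.
    sensor_range
        Declared wavelength span of the sensor, nm.
    """

    values: np.ndarray
    wavelengths: np.ndarray
    meta: dict = field(default_factory=dict)
    calibrated: bool = False
    sensor_range: tuple[float, float] = DEFAULT_SENSOR_RANGE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64).ravel()
        if self.values.ndim != 3:
            raise ValueError(f"cube values must be 3-D (y, x, band), got ndim={self.values.ndim}")
        if self.values.size == 0:
            raise ValueError("empty cube")
        if self.wavelengths.size != self.values.shape[2]:
            raise ValueError(
                "wavelength count mismatch: "
                f"{self.wavelengths.size} wavelengths for {self.values.shape[2]} bands"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        lo, hi = self.sensor_range
        if self.wavelengths[0] < lo - 1e-9 or self.wavelengths[-1] > hi + 1e-9:
            raise ValueError(
                f"wavelengths [{self.wavelengths[0]:g}, {self.wavelengths[-1]:g}] nm "
                f"outside sensor range [{lo:g}, {hi:g}] nm"
            )
        if self.calibrated and not np.all(np.isfinite(self.values)):
            raise ValueError("calibrated cube contains non-finite reflectance")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]

    def transpose_spatial(self) -> "SpectralCube":
        """Swap the two spatial axes (for inputs scanned the other way round)."""
        return SpectralCube(
            np.swapaxes(self.values, 0, 1),
            self.wavelengths,
            dict(self.meta),
            calibrated=self.calibrated,
            sensor_range=self.sensor_range,
        )

    def __eq__(self, other: object) -> bool:  # value equality, used by round-trip tests
        if not isinstance(other, SpectralCube):
            return NotImplemented
        return (
            self.values.shape == other.values.shape
            and np.array_equal(self.values, other.values)
            and np.allclose(self.wavelengths, other.wavelengths)
        )


def band_index(cube: SpectralCube, target_nm: float) -> int:
    """Index of the band whose centre wavelength is nearest ``target_nm``.

    Equidistant ties resolve to the lower index.  Targets outside the cube's
    wavelength span raise ``ValueError``.
    """
    w = cube.wavelengths
    if target_nm < w[0] or target_nm > w[-1]:
        raise ValueError(
            f"target wavelength {target_nm:g} nm outside cube range [{w[0]:g}, {w[-1]:g}] nm"
        )
    return int(np.argmin(np.abs(w - target_nm)))


FrameLike = Union[np.ndarray, SpectralCube]


@dataclass
class ReferenceSet:
    """Dark-current and white-reference data for reflectance calibration.

    ``dark`` and ``white`` may each be a (row, band) frame — one calibration
    reading per sensor-line pixel — or a full cube, which is averaged over
    the scan (column) axis to a frame.
    """

    dark: FrameLike
    white: FrameLike

    def frames_for(self, cube: SpectralCube) -> tuple[np.ndarray, np.ndarray]:
        """Return (dark, white) as float64 (row, band) frames matching ``cube``."""
        return (
            _as_frame(self.dark, cube, "dark"),
            _as_frame(self.white, cube, "white"),
        )


def _as_frame(ref: FrameLike, cube: SpectralCube, name: str) -> np.ndarray:
    if isinstance(ref, SpectralCube):
        arr = np.asarray(ref.values, dtype=np.float64).mean(axis=1)
    else:
        arr = np.asarray(ref, dtype=np.float64)
        if arr.ndim == 3:
            arr = arr.mean(axis=1)
    if arr.ndim != 2 or arr.shape != (cube.n_rows, cube.n_bands):
        raise ValueError(
            f"{name} reference shape {arr.shape} incompatible with cube "
            f"(expected ({cube.n_rows}, {cube.n_bands}))"
        )
    return arr


def calibrate(
    raw: SpectralCube,
    refs: ReferenceSet,
    denominator: str = "white_plus_dark",
) -> SpectralCube:
    """Convert raw counts to reflectance against dark and white references.

    The default form is ``(R_raw - R_dark) / (R_white + R_dark)``; pass
    ``denominator="white_minus_dark"`` for the conventional flat-field
    correction.  Computation is float64 regardless of the raw dtype.
    Any zero in the denominator raises ``ValueError``.
    """
    if denominator not in ("white_plus_dark", "white_minus_dark"):
        raise ValueError(f"unknown denominator form {denominator!r}")
    dark, white = refs.frames_for(raw)
    den = white + dark if denominator == "white_plus_dark" else white - dark
    if np.any(den == 0):
        raise ValueError("zero denominator in calibration reference")
    out = (raw.values.astype(np.float64) - dark[:, None, :]) / den[:, None, :]
    meta = dict(raw.meta)
    meta["calibration"] = denominator
    return SpectralCube(
        out, raw.wavelengths, meta, calibrated=True, sensor_range=raw.sensor_range
    )


# ---------------------------------------------------------------------------
# ENVI header + binary I/O
# ---------------------------------------------------------------------------

def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().lower().startswith("envi"):
        raise ValueError("not an ENVI header (missing 'ENVI' magic line)")
    body = text.lstrip()[4:]
    fields: dict[str, str] = {}
    # key = value, where value may be a {...} block spanning lines
    pattern = re.compile(r"^\s*([\w ]+?)\s*=\s*(\{.*?\}|[^\n]*)", re.S | re.M)
    pos = 0
    while pos < len(body):
        m = pattern.search(body, pos)
        if m is None:
            break
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        fields[key] = val
        pos = m.end()
    return fields


def _parse_list(value: str) -> list[float]:
    inner = value.strip().lstrip("{").rstrip("}")
    return [float(tok) for tok in inner.replace("\n", " ").split(",") if tok.strip()]


def _locate_binary(header_path: Path, interleave: str) -> Path:
    base = header_path.with_suffix("")
    candidates = [
        base.with_suffix(f".{interleave}"),
        base.with_suffix(".img"),
        base.with_suffix(".dat"),
        base,
    ]
    for cand in candidates:
        if cand.exists() and cand.is_file():
            return cand
    raise FileNotFoundError(
        f"missing binary for ENVI header {header_path}: tried "
        + ", ".join(str(c) for c in candidates)
    )


def read_envi_cube(header_path: str | Path) -> SpectralCube:
    """Read an ENVI header (.hdr) + binary cube into a :class:`SpectralCube`.

    Honours the header keys ``samples``, ``lines``, ``bands``, ``interleave``,
    ``data type``, ``byte order`` and ``wavelength``.  BIL, BIP and BSQ
    interleaves are supported; the result is always indexed (line, sample,
    band).
    """
    header_path = Path(header_path)
    fields = _parse_envi_header(header_path.read_text())
    for required in ("samples", "lines", "bands", "data type", "interleave"):
        if required not in fields:
            raise ValueError(f"ENVI header missing field '{required}'")
    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    interleave = fields["interleave"].strip().lower()
    if interleave not in _INTERLEAVES:
        raise ValueError(f"unsupported interleave '{interleave}' (expected bil, bip or bsq)")
    dcode = int(fields["data type"])
    if dcode not in _ENVI_TO_NUMPY:
        raise ValueError(f"unsupported ENVI data type code {dcode}")
    dtype = np.dtype(_ENVI_TO_NUMPY[dcode])
    if int(fields.get("byte order", "0")) == 1:
        dtype = dtype.newbyteorder(">")
    if "wavelength" not in fields:
        raise ValueError("ENVI header missing field 'wavelength'")
    wavelengths = np.array(_parse_list(fields["wavelength"]))
    if wavelengths.size != bands:
        raise ValueError(
            f"wavelength count mismatch: {wavelengths.size} wavelengths for {bands} bands"
        )

    binary = _locate_binary(header_path, interleave)
    flat = np.fromfile(binary, dtype=dtype)
    if flat.size != samples * lines * bands:
        raise ValueError(
            f"binary size mismatch: {flat.size} values for "
            f"{lines} lines x {samples} samples x {bands} bands"
        )
    if interleave == "bip":
        values = flat.reshape(lines, samples, bands)
    elif interleave == "bil":
        values = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bsq
        values = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    values = np.ascontiguousarray(values.astype(dtype.newbyteorder("=")))

    meta = {
        k: v
        for k, v in fields.items()
        if k not in ("samples", "lines", "bands", "data type", "interleave",
                     "byte order", "wavelength", "header offset", "file type",
                     "wavelength units")
    }
    calibrated = str(meta.pop("calibrated", "0")).strip().lower() in ("1", "true", "yes")
    lo = min(DEFAULT_SENSOR_RANGE[0], float(wavelengths[0]))
    hi = max(DEFAULT_SENSOR_RANGE[1], float(wavelengths[-1]))
    return SpectralCube(values, wavelengths, meta, calibrated=calibrated, sensor_range=(lo, hi))


def write_envi_cube(
    cube: SpectralCube,
    path: str | Path,
    interleave: str = "bil",
    dtype: np.dtype | str = np.float32,
) -> Path:
    """Write ``cube`` as an ENVI header + binary pair; returns the header path.

    ``path`` may be the header path (``.hdr``) or a bare base path.  The
    binary sits next to the header with the interleave as its extension.
    Storage dtype defaults to float32.
    """
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise ValueError(f"unsupported interleave '{interleave}'")
    dtype = np.dtype(dtype)
    if dtype not in _NUMPY_TO_ENVI:
        raise ValueError(f"dtype {dtype} has no ENVI data-type code")
    path = Path(path)
    header_path = path if path.suffix == ".hdr" else path.with_suffix(".hdr")
    binary_path = header_path.with_suffix(f".{interleave}")
    header_path.parent.mkdir(parents=True, exist_ok=True)

    arr = cube.values.astype(dtype)
    if interleave == "bip":
        disk = arr
    elif interleave == "bil":
        disk = arr.transpose(0, 2, 1)
    else:  # bsq
        disk = arr.transpose(2, 0, 1)
    np.ascontiguousarray(disk).tofile(binary_path)

    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    lines = [
        "ENVI",
        f"samples = {cube.n_cols}",
        f"lines = {cube.n_rows}",
        f"bands = {cube.n_bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_NUMPY_TO_ENVI[dtype]}",
        f"interleave = {interleave}",
        "byte order = 0",
        "wavelength units = Nanometers",
        f"calibrated = {int(cube.calibrated)}",
        f"wavelength = {{ {wl} }}",
    ]
    header_path.write_text("\n".join(lines) + "\n")
    return header_path
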