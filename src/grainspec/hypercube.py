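"""Hypercube container, ENVI I/O and push-broom radiometric calibration.

A push-broom NIR imager records one detector frame (samples x bands) per
spatial line while the tray translates under the slit.  Raw detector counts
are converted to reflectance against black (shutter closed) and white (PTFE
panel) reference frames, and then to absorbance A = log10(1/R), the quantity
all downstream chemometrics operate on.

The ENVI dialect supported here is the plain-text ``.hdr`` plus flat binary
file with keys ``samples``, ``lines``, ``bands``, ``interleave`` (bil/bip/bsq),
``data type``, ``byte order`` and a ``wavelength`` block in nm.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "WavelengthGrid",
    "Hypercube",
    "ReferencePair",
    "read_envi",
    "write_envi",
    "compute_reflectance",
    "to_absorbance",
]

STAGES = ("raw_counts", "reflectance", "absorbance")

# ENVI numeric codes for the dtypes this package reads and writes.
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing band centres in nm, restricted to the NIR window."""

    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError("wavelength grid needs at least 2 bands")
        if not np.all(np.diff(vals) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if vals[0] < 900 or vals[-1] > 2600:
            raise ValueError("wavelengths must lie in [900, 2600] nm")

    def __len__(self) -> int:
        return self.values.size

    def nearest_band(self, wavelength_nm: float) -> int:
        """Index of the band centre closest to ``wavelength_nm``."""
        if not (self.values[0] <= wavelength_nm <= self.values[-1]):
            raise ValueError(
                f"{wavelength_nm} nm outside grid span "
                f"[{self.values[0]}, {self.values[-1]}]"
            )
        return int(np.argmin(np.abs(self.values - wavelength_nm)))

    def band_slice(self, lo_nm: float, hi_nm: float) -> np.ndarray:
        """Boolean mask of bands with lo_nm <= wavelength <= hi_nm."""
        if lo_nm >= hi_nm:
            raise ValueError("need lo_nm < hi_nm")
        mask = (self.values >= lo_nm) & (self.values <= hi_nm)
        if not mask.any():
            raise ValueError("no bands in requested range")
        return mask


@dataclass
class Hypercube:
    """(lines, samples, bands) image with a wavelength grid and stage tag.

    ``stage`` records where the cube sits in the raw -> reflectance ->
    absorbance chain; operations check it so that, e.g., absorbance is never
    taken twice.
    """

    data: np.ndarray
    grid: WavelengthGrid
    stage: str = "raw_counts"
    pixel_size_mm: float = 0.109

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("hypercube data must be 3-D (lines, samples, bands)")
        if self.data.shape[2] != len(self.grid):
            raise ValueError(
                f"{self.data.shape[2]} bands in data vs {len(self.grid)} wavelengths"
            )
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_lines(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclass
class ReferencePair:
    """Mean black (dark current) and white (PTFE) reference frames.

    Both are (samples, bands): each detector column is a fixed physical
    element in a push-broom camera, so references are applied per column
    and band.
    """

    black: np.ndarray
    white: np.ndarray
    n_black_frames: int = 1
    n_white_frames: int = 1

    def __post_init__(self):
        self.black = np.asarray(self.black, dtype=np.float64)
        self.white = np.asarray(self.white, dtype=np.float64)
        if self.black.shape != self.white.shape or self.black.ndim != 2:
            raise ValueError("black and white must be 2-D (samples, bands) and match")

    def validate(self) -> None:
        if not np.all(self.white > self.black):
            bad = int(np.sum(self.white <= self.black))
            raise ValueError(
                f"white <= black at {bad} (sample, band) positions; "
                "references unusable"
            )


# ---------------------------------------------------------------------------
# ENVI I/O


def _parse_header(text: str) -> dict:
    if not text.lstrip().lower().startswith("envi"):
        raise ValueError("not an ENVI header (missing 'ENVI' magic)")
    body = text.lstrip()[4:]
    fields: dict[str, str] = {}
    # key = value pairs; {...} blocks may span lines
    pattern = re.compile(r"^\s*([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.M | re.S)
    for m in pattern.finditer(body):
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        if val.startswith("{"):
            val = val[1:-1]
        fields[key] = val
    return fields


def write_envi(cube: Hypercube, header_path, data_path=None, *, interleave="bil",
               dtype=None) -> Path:
    """Write an ENVI header + binary pair; returns the data path.

    Raw counts default to 16-bit unsigned, calibrated stages to 32-bit float.
    """
    header_path = Path(header_path)
    if data_path is None:
        data_path = header_path.with_suffix(".dat")
    data_path = Path(data_path)
    interleave = interleave.lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise ValueError(f"unsupported interleave {interleave!r}")
    if dtype is None:
        dtype = np.uint16 if cube.stage == "raw_counts" else np.float32
    dtype = np.dtype(dtype)
    if dtype not in _DTYPE_CODES:
        raise ValueError(f"unsupported ENVI dtype {dtype}")

    arr = cube.data  # internal layout is (L, S, B) == BIP line-major
    if interleave == "bip":
        out = arr
    elif interleave == "bil":
        out = arr.transpose(0, 2, 1)  # (L, B, S)
    else:  # bsq
        out = arr.transpose(2, 0, 1)  # (B, L, S)
    out = np.ascontiguousarray(out, dtype=dtype.newbyteorder("<"))
    out.tofile(data_path)

    wl = ", ".join(f"{w:.6f}" for w in cube.grid.values)
    lines = [
        "ENVI",
        "description = {grainspec hypercube}",
        f"samples = {cube.n_samples}",
        f"lines = {cube.n_lines}",
        f"bands = {cube.n_bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_DTYPE_CODES[dtype]}",
        f"interleave = {interleave}",
        "byte order = 0",
        "wavelength units = Nanometers",
        f"stage = {cube.stage}",
        f"pixel size mm = {cube.pixel_size_mm}",
        "wavelength = {" + wl + "}",
    ]
    header_path.write_text("\n".join(lines) + "\n")
    return data_path


def read_envi(header_path, data_path=None) -> Hypercube:
    """Read an ENVI cube; interleave is normalised to (lines, samples, bands)."""
    header_path = Path(header_path)
    fields = _parse_header(header_path.read_text())
    for key in ("samples", "lines", "bands", "interleave", "data type"):
        if key not in fields:
            raise ValueError(f"ENVI header missing required key {key!r}")
    if "wavelength" not in fields:
        raise ValueError("ENVI header missing wavelength block")

    n_samples = int(fields["samples"])
    n_lines = int(fields["lines"])
    n_bands = int(fields["bands"])
    code = int(fields["data type"])
    if code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type code {code}")
    dtype = np.dtype(_ENVI_DTYPES[code])
    byte_order = int(fields.get("byte order", "0"))
    dtype = dtype.newbyteorder("<" if byte_order == 0 else ">")
    interleave = fields["interleave"].lower()
    wavelengths = np.array(
        [float(t) for t in fields["wavelength"].replace("\n", " ").split(",") if t.strip()]
    )
    if wavelengths.size != n_bands:
        raise ValueError(
            f"header declares {n_bands} bands but {wavelengths.size} wavelengths"
        )

    if data_path is None:
        data_path = header_path.with_suffix(".dat")
        if not Path(data_path).exists():
            raise FileNotFoundError(f"no data file next to header: {data_path}")
    raw = np.fromfile(data_path, dtype=dtype)
    expected = n_lines * n_samples * n_bands
    if raw.size != expected:
        raise ValueError(f"data file has {raw.size} values, expected {expected}")

    if interleave == "bip":
        arr = raw.reshape(n_lines, n_samples, n_bands)
    elif interleave == "bil":
        arr = raw.reshape(n_lines, n_bands, n_samples).transpose(0, 2, 1)
    elif interleave == "bsq":
        arr = raw.reshape(n_bands, n_lines, n_samples).transpose(1, 2, 0)
    else:
        raise ValueError(f"unsupported interleave {interleave!r}")

    stage = fields.get("stage", "raw_counts")
    pixel = float(fields.get("pixel size mm", "0.109"))
    return Hypercube(
        data=np.ascontiguousarray(arr),
        grid=WavelengthGrid(wavelengths),
        stage=stage,
        pixel_size_mm=pixel,
    )


# ---------------------------------------------------------------------------
# Radiometric calibration


def compute_reflectance(raw: Hypercube, refs: ReferencePair) -> Hypercube:
    """(raw - black) / (white - black), per detector column and band.

    No clipping: reflectance may exceed 1 (specular glints) or fall below 0
    (noise around very dark pixels); the absorbance step handles the floor.
    """
    if raw.stage != "raw_counts":
        raise ValueError(f"expected raw_counts cube, got stage {raw.stage!r}")
    refs.validate()
    if refs.black.shape != (raw.n_samples, raw.n_bands):
        raise ValueError("reference frames do not match cube (samples, bands)")
    denom = refs.white - refs.black  # (S, B), broadcast over lines
    refl = (raw.data.astype(np.float64) - refs.black[None]) / denom[None]
    return Hypercube(refl.astype(np.float32), raw.grid, "reflectance",
                     raw.pixel_size_mm)


def to_absorbance(refl: Hypercube, floor: float = 1e-4) -> tuple[Hypercube, int]:
    """A = log10(1 / max(R, floor)); returns the cube and the floored-pixel count."""
    if refl.stage != "reflectance":
        raise ValueError(f"expected reflectance cube, got stage {refl.stage!r}")
    if floor <= 0:
        raise ValueError("floor must be positive")
    r = refl.data.astype(np.float64)
    n_floored = int(np.sum(r < floor))
    absb = -np.log10(np.maximum(r, floor))
    cube = Hypercube(absb.astype(np.float32), refl.grid, "absorbance",
                     refl.pixel_size_mm)
    return cube, n_floored
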