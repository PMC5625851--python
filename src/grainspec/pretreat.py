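"""Spectral pretreatments applied identically at calibration and prediction.

All transforms take (n_spectra, n_bands) matrices (1-D input is promoted) and
are composed through :class:`PretreatmentSpec`, an ordered, serialisable step
list.  Any parameter learned from the calibration set (the MSC "training
mean" reference) is frozen into the spec at fit time and reused verbatim at
prediction time — including per-pixel prediction mapping.
"""

from __future__ import annotations

import json

import numpy as np
from scipy.signal import savgol_filter

from .hypercube import WavelengthGrid
from .pipeline import SpectraTable

__all__ = [
    "snv",
    "msc",
    "detrend",
    "savgol",
    "normalise",
    "baseline",
    "restrict_range",
    "PretreatmentSpec",
]


def _as_matrix(x) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        return x[None, :], True
    if x.ndim != 2:
        raise ValueError("expected 1-D spectrum or 2-D spectra matrix")
    return x, False


def _restore(x: np.ndarray, was_1d: bool) -> np.ndarray:
    return x[0] if was_1d else x


def snv(x) -> np.ndarray:
    """Standard normal variate: per-spectrum centre and scale to unit sample sd."""
    X, was_1d = _as_matrix(x)
    if X.shape[1] < 2:
        raise ValueError("SNV needs at least 2 bands")
    sd = X.std(axis=1, ddof=1)
    if np.any(sd < 1e-12):
        raise ValueError("SNV undefined for a constant spectrum")
    out = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    return _restore(out, was_1d)


def msc(x, reference) -> np.ndarray:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum is regressed as x ~ a + b * reference (ordinary least
    squares); the corrected spectrum is (x - a) / b.
    """
    X, was_1d = _as_matrix(x)
    ref = np.asarray(reference, dtype=np.float64)
    if ref.shape != (X.shape[1],):
        raise ValueError("reference must match the band count")
    if ref.std() < 1e-12:
        raise ValueError("MSC reference must not be constant")
    design = np.column_stack([np.ones_like(ref), ref])
    coef, *_ = np.linalg.lstsq(design, X.T, rcond=None)  # (2, n_spectra)
    a, b = coef
    if np.any(np.abs(b) < 1e-8):
        raise ValueError("MSC slope vanishes for at least one spectrum")
    out = (X - a[:, None]) / b[:, None]
    return _restore(out, was_1d)


def detrend(x, wavelengths, order: int = 2) -> np.ndarray:
    """Subtract the least-squares polynomial in wavelength of given order."""
    X, was_1d = _as_matrix(x)
    wl = np.asarray(wavelengths, dtype=np.float64)
    if order < 1:
        raise ValueError("detrend order must be >= 1")
    if X.shape[1] <= order:
        raise ValueError("detrend order must be below the band count")
    # centred/scaled wavelength for conditioning; same column span
    span = float(wl.max() - wl.min())
    t = (wl - wl.mean()) / (span / 2 if span else 1.0)
    basis = np.vander(t, order + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(basis, X.T, rcond=None)
    out = X - (basis @ coef).T
    return _restore(out, was_1d)


def savgol(x, window: int = 5, polyorder: int = 2, deriv: int = 0) -> np.ndarray:
    """Savitzky-Golay smoothing / derivative, per-band-index units.

    Edges are handled by a one-sided polynomial fit (same output length).
    """
    X, was_1d = _as_matrix(x)
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and greater than polyorder")
    if deriv > polyorder:
        raise ValueError("derivative order must not exceed polyorder")
    if window > X.shape[1]:
        raise ValueError("window exceeds band count")
    out = savgol_filter(X, window, polyorder, deriv=deriv, delta=1.0,
                        axis=1, mode="interp")
    return _restore(out, was_1d)


def normalise(x, mode: str = "unit_area") -> np.ndarray:
    """Scale each spectrum so the chosen functional equals one.

    Modes: unit_area (trapezoidal area, unit band spacing), unit_length
    (Euclidean norm), max_one (maximum absolute value).
    """
    X, was_1d = _as_matrix(x)
    if mode == "unit_area":
        scale = np.trapezoid(X, axis=1)
    elif mode == "unit_length":
        scale = np.linalg.norm(X, axis=1)
    elif mode == "max_one":
        scale = np.max(np.abs(X), axis=1)
    else:
        raise ValueError(f"unknown normalisation mode {mode!r}")
    if np.any(np.abs(scale) < 1e-12):
        raise ValueError("cannot normalise a zero-norm spectrum")
    return _restore(X / scale[:, None], was_1d)


def baseline(x, mode: str = "offset_min") -> np.ndarray:
    """Subtract a per-spectrum scalar offset (minimum or first band)."""
    X, was_1d = _as_matrix(x)
    if mode == "offset_min":
        off = X.min(axis=1)
    elif mode == "offset_first":
        off = X[:, 0]
    else:
        raise ValueError(f"unknown baseline mode {mode!r}")
    return _restore(X - off[:, None], was_1d)


def restrict_range(table: SpectraTable, lo_nm: float, hi_nm: float) -> SpectraTable:
    """Keep bands with lo_nm <= wavelength <= hi_nm; rows and metadata intact."""
    mask = table.grid.band_slice(lo_nm, hi_nm)
    return SpectraTable(table.spectra[:, mask],
                        WavelengthGrid(table.grid.values[mask]), table.records)


# ---------------------------------------------------------------------------


_STEP_NAMES = {"snv", "msc", "detrend", "savgol", "normalise", "baseline",
               "range"}


class PretreatmentSpec:
    """Ordered, parameterised pretreatment chain.

    Steps are dicts with a ``step`` key, e.g.::

        PretreatmentSpec([{"step": "snv"},
                          {"step": "savgol", "window": 5, "polyorder": 2,
                           "deriv": 1}])

    ``fit`` runs the chain on the calibration table and freezes any
    data-dependent parameters (currently the MSC training-mean reference);
    ``apply`` then reproduces the identical transform on any input.
    """

    def __init__(self, steps: list[dict] | None = None, name: str | None = None):
        self.steps = [dict(s) for s in (steps or [])]
        self.name = name
        for s in self.steps:
            kind = s.get("step")
            if kind not in _STEP_NAMES:
                raise ValueError(f"unknown pretreatment step {kind!r}")
            if kind == "savgol":
                w, p = s.get("window", 5), s.get("polyorder", 2)
                d = s.get("deriv", 0)
                if w % 2 == 0 or w <= p or d > p:
                    raise ValueError("invalid savgol parameters")
            if kind == "range" and not s.get("lo", 0) < s.get("hi", 0):
                raise ValueError("range step needs lo < hi")

    @property
    def fitted(self) -> bool:
        return all("frozen_reference" in s for s in self.steps
                   if s["step"] == "msc"
                   and s.get("reference", "training_mean") == "training_mean")

    def _run(self, X: np.ndarray, grid: WavelengthGrid, *, fitting: bool
             ) -> tuple[np.ndarray, WavelengthGrid]:
        for s in self.steps:
            kind = s["step"]
            if kind == "snv":
                X = snv(X)
            elif kind == "msc":
                ref_mode = s.get("reference", "training_mean")
                if isinstance(ref_mode, str) and ref_mode == "training_mean":
                    if fitting:
                        s["frozen_reference"] = X.mean(axis=0).tolist()
                    if "frozen_reference" not in s:
                        raise ValueError("MSC training mean not fitted; call "
                                         "fit() on the calibration set first")
                    ref = np.asarray(s["frozen_reference"])
                else:
                    ref = np.asarray(ref_mode, dtype=float)
                X = msc(X, ref)
            elif kind == "detrend":
                X = detrend(X, grid.values, order=s.get("order", 2))
            elif kind == "savgol":
                X = savgol(X, s.get("window", 5), s.get("polyorder", 2),
                           s.get("deriv", 0))
            elif kind == "normalise":
                X = normalise(X, s.get("mode", "unit_area"))
            elif kind == "baseline":
                X = baseline(X, s.get("mode", "offset_min"))
            elif kind == "range":
                mask = grid.band_slice(s["lo"], s["hi"])
                X = X[:, mask]
                grid = WavelengthGrid(grid.values[mask])
        return X, grid

    def fit(self, table: SpectraTable) -> "PretreatmentSpec":
        self._run(table.spectra, table.grid, fitting=True)
        return self

    def apply_matrix(self, X: np.ndarray, grid: WavelengthGrid
                     ) -> tuple[np.ndarray, WavelengthGrid]:
        return self._run(np.asarray(X, dtype=np.float64), grid, fitting=False)

    def apply(self, table: SpectraTable) -> SpectraTable:
        X, grid = self.apply_matrix(table.spectra, table.grid)
        return SpectraTable(X, grid, table.records)

    # -- serialisation ----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({"name": self.name, "steps": self.steps}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PretreatmentSpec":
        raw = json.loads(text)
        return cls(raw["steps"], name=raw.get("name"))

    def __repr__(self) -> str:
        label = self.name or "+".join(s["step"] for s in self.steps) or "identity"
        return f"PretreatmentSpec({label})"
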