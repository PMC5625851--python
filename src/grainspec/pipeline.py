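"""Kernel image pipeline: spike repair, segmentation, indexing, mean spectra.

Operates on absorbance hypercubes.  Spikes (bad detector events affecting a
single pixel at a single band) are detected per band against the spatial
median of a small window with a robust MAD threshold, and repaired by
interpolation along the spectral axis of the affected pixel — the scene is
smooth in wavelength everywhere, including kernel/tray boundaries where a
spatial median is biased.  Kernels are segmented with the single-band rule
absorbance(1186 nm) < 0.9, labelled 8-connected, and indexed (row, position)
in reading order on the two-row tray.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .hypercube import Hypercube, WavelengthGrid

__all__ = [
    "KernelRecord",
    "SpectraTable",
    "LabelMap",
    "SpikeReport",
    "remove_spikes",
    "segment_kernels",
    "label_and_index",
    "extract_mean_spectra",
]


@dataclass
class KernelRecord:
    """Metadata for one segmented kernel-orientation."""

    kernel_id: int
    batch: int = 0
    row: int = 0
    position: int = 0
    orientation: str = "unknown"
    area_px: int = 0
    pixel_size_mm: float = 0.109
    protein_ref: float | None = None
    weight_ref: float | None = None
    hardness: str | None = None

    def __post_init__(self):
        if self.protein_ref is not None and not np.isnan(self.protein_ref):
            if not 0 < self.protein_ref < 100:
                raise ValueError(f"protein {self.protein_ref} outside (0, 100)%")

    @property
    def area_mm2(self) -> float:
        return self.area_px * self.pixel_size_mm ** 2


@dataclass
class SpectraTable:
    """N kernel-mean absorbance spectra with aligned metadata and one grid."""

    spectra: np.ndarray
    grid: WavelengthGrid
    records: list[KernelRecord]

    def __post_init__(self):
        self.spectra = np.asarray(self.spectra, dtype=np.float64)
        if self.spectra.ndim != 2 or self.spectra.shape[1] != len(self.grid):
            raise ValueError("spectra must be (n_records, n_bands)")
        if self.spectra.shape[0] != len(self.records):
            raise ValueError(f"{self.spectra.shape[0]} spectra vs "
                             f"{len(self.records)} records")
        if not np.all(np.isfinite(self.spectra)):
            raise ValueError("non-finite values in spectra")

    def __len__(self) -> int:
        return len(self.records)

    def response(self, name: str) -> np.ndarray:
        """Aligned reference values; name is 'protein' or 'weight'."""
        attr = {"protein": "protein_ref", "weight": "weight_ref"}[name]
        vals = np.array([getattr(r, attr) for r in self.records], dtype=float)
        if np.any(np.isnan(vals)):
            raise ValueError(f"missing {name} reference values")
        return vals

    def grain_ids(self) -> np.ndarray:
        return np.array([r.kernel_id for r in self.records])

    def subset(self, mask: np.ndarray) -> "SpectraTable":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return SpectraTable(self.spectra[idx], self.grid,
                            [self.records[i] for i in idx])

    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "id": r.kernel_id, "batch": r.batch, "row": r.row,
            "position": r.position, "orientation": r.orientation,
            "hardness": r.hardness, "area_px": r.area_px,
            "area_mm2": r.area_mm2, "protein_ref": r.protein_ref,
            "weight_ref": r.weight_ref} for r in self.records])

    # -- CSV round-trip: one row per kernel-orientation, band columns by nm --
    def to_dataframe(self) -> pd.DataFrame:
        meta = self.metadata()
        bands = pd.DataFrame(self.spectra,
                             columns=[f"{w:.6f}" for w in self.grid.values])
        return pd.concat([meta, bands], axis=1)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectraTable":
        df = pd.read_csv(path)
        meta_cols = ["id", "batch", "row", "position", "orientation",
                     "hardness", "area_px", "area_mm2", "protein_ref",
                     "weight_ref"]
        band_cols = [c for c in df.columns if c not in meta_cols]
        grid = WavelengthGrid(np.array([float(c) for c in band_cols]))
        records = []
        for _, r in df.iterrows():
            records.append(KernelRecord(
                kernel_id=int(r["id"]), batch=int(r["batch"]),
                row=int(r["row"]), position=int(r["position"]),
                orientation=r["orientation"],
                hardness=None if pd.isna(r.get("hardness")) else r["hardness"],
                area_px=int(r["area_px"]),
                pixel_size_mm=float(np.sqrt(r["area_mm2"] / r["area_px"]))
                if r["area_px"] else 0.109,
                protein_ref=None if pd.isna(r["protein_ref"]) else float(r["protein_ref"]),
                weight_ref=None if pd.isna(r["weight_ref"]) else float(r["weight_ref"]),
            ))
        return cls(df[band_cols].to_numpy(dtype=float), grid, records)


@dataclass
class LabelMap:
    """Integer label image: 0 = tray/background, 1..K = kernels in reading order."""

    labels: np.ndarray
    counts: np.ndarray           # pixel count per label, index 0 unused
    centroids: np.ndarray        # (K+1, 2) (line, sample), index 0 unused
    rows: np.ndarray             # row index per label, index 0 unused
    positions: np.ndarray        # within-row position per label, index 0 unused
    dropped: list = field(default_factory=list)  # (label size) removed as debris

    @property
    def n_kernels(self) -> int:
        return int(self.labels.max())


@dataclass
class SpikeReport:
    """Every modification made by remove_spikes, one row per (pixel, band)."""

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)


def remove_spikes(cube: Hypercube, window: int = 3, k: float = 6.0,
                  min_scale: float = 0.025) -> tuple[Hypercube, SpikeReport]:
    """Detect and repair single-pixel spikes in an absorbance cube.

    Detection (per band): a pixel whose absolute deviation from the spatial
    median of its ``window`` x ``window`` neighbourhood exceeds
    ``k * max(1.4826 * MAD_band, min_scale)`` is flagged; MAD_band is the
    median absolute deviation of that band's deviation image.  ``min_scale``
    is an absolute absorbance floor that keeps the threshold meaningful on
    near-noise-free data.  Repair replaces each flagged (pixel, band) by
    linear interpolation over the pixel's unflagged bands.  Idempotent:
    repaired values sit below threshold on a second pass.
    """
    if cube.stage != "absorbance":
        raise ValueError(f"expected absorbance cube, got {cube.stage!r}")
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if k <= 0:
        raise ValueError("k must be positive")

    data = cube.data.astype(np.float64, copy=True)
    work = data.astype(np.float32)
    n_l, n_s, n_b = work.shape
    half = window // 2
    mid = window * window // 2
    flagged = np.empty((n_l, n_s, n_b), dtype=bool)
    med = np.empty_like(work)
    # per band: window median via a partition over stacked shifted views,
    # then the robust MAD threshold of that band's deviation image
    for b in range(n_b):
        padded = np.pad(work[:, :, b], half, mode="edge")
        stack = np.stack([padded[i:i + n_l, j:j + n_s]
                          for i in range(window) for j in range(window)])
        med_b = np.partition(stack, mid, axis=0)[mid]
        dev = work[:, :, b] - med_b
        absdev = np.abs(dev)
        mad = np.partition(absdev.ravel(), absdev.size // 2)[absdev.size // 2]
        thresh_b = k * max(1.4826 * float(mad), min_scale)
        med[:, :, b] = med_b
        flagged[:, :, b] = absdev > thresh_b

    rows = []
    if flagged.any():
        n_bands = cube.n_bands
        band_idx = np.arange(n_bands)
        px_lines, px_samples = np.nonzero(flagged.any(axis=2))
        for l, s in zip(px_lines, px_samples):
            bad = flagged[l, s]
            good = ~bad
            spectrum = data[l, s]
            if good.sum() >= 2:
                repaired = np.interp(band_idx[bad], band_idx[good],
                                     spectrum[good])
            else:  # pathological: whole spectrum flagged; fall back to median
                repaired = med[l, s, bad]
            for b, new in zip(band_idx[bad], np.atleast_1d(repaired)):
                rows.append((int(l), int(s), int(b),
                             float(data[l, s, b]), float(new)))
                data[l, s, b] = new
    report = SpikeReport(pd.DataFrame(
        rows, columns=["line", "sample", "band", "old", "new"]))
    out = Hypercube(data, cube.grid, "absorbance", cube.pixel_size_mm)
    return out, report


def segment_kernels(cube: Hypercube, wavelength_nm: float = 1186.0,
                    threshold: float = 0.9) -> np.ndarray:
    """Binary kernel mask: absorbance at the band nearest ``wavelength_nm``
    strictly below ``threshold`` (the tray is NIR-absorbent there)."""
    if cube.stage != "absorbance":
        raise ValueError(f"expected absorbance cube, got {cube.stage!r}")
    band = cube.grid.nearest_band(wavelength_nm)
    return cube.data[:, :, band] < threshold


_EIGHT = np.ones((3, 3), dtype=int)


def label_and_index(mask: np.ndarray, min_area_px: int = 20,
                    n_rows: int = 2) -> LabelMap:
    """8-connected components, debris-filtered, indexed in tray reading order.

    Rows are found by splitting the sorted component centroid line-coordinates
    at the ``n_rows - 1`` largest gaps; within a row kernels are ordered by
    sample coordinate.  Raises if the centroids cannot be split into the
    requested number of non-empty rows.
    """
    mask = np.asarray(mask, dtype=bool)
    raw_labels, n_found = ndimage.label(mask, structure=_EIGHT)
    if n_found == 0:
        empty = np.zeros(1)
        return LabelMap(labels=raw_labels, counts=np.zeros(1, dtype=int),
                        centroids=np.zeros((1, 2)), rows=empty.astype(int),
                        positions=empty.astype(int))

    counts = np.bincount(raw_labels.ravel(), minlength=n_found + 1)
    keep = [i for i in range(1, n_found + 1) if counts[i] >= min_area_px]
    dropped = [(i, int(counts[i])) for i in range(1, n_found + 1)
               if counts[i] < min_area_px]
    if not keep:
        labels = np.zeros_like(raw_labels)
        z = np.zeros(1)
        return LabelMap(labels=labels, counts=np.zeros(1, dtype=int),
                        centroids=np.zeros((1, 2)), rows=z.astype(int),
                        positions=z.astype(int), dropped=dropped)

    cents = np.array(ndimage.center_of_mass(mask, raw_labels, keep))
    lines = cents[:, 0]
    order = np.argsort(lines)
    if n_rows > len(keep):
        raise ValueError(f"cannot split {len(keep)} kernels into {n_rows} rows")
    if n_rows == 1:
        row_of = np.zeros(len(keep), dtype=int)
    else:
        gaps = np.diff(lines[order])
        cut_positions = np.sort(np.argsort(gaps)[-(n_rows - 1):])
        row_sorted = np.zeros(len(keep), dtype=int)
        r = 0
        for i in range(1, len(keep)):
            if (i - 1) in cut_positions:
                r += 1
            row_sorted[i] = r
        row_of = np.empty(len(keep), dtype=int)
        row_of[order] = row_sorted
        if len(np.unique(row_of)) != n_rows:
            raise ValueError("row clustering failed: centroid line coordinates "
                             f"do not separate into {n_rows} rows")

    # reading order: row ascending, then sample coordinate ascending
    reading = sorted(range(len(keep)), key=lambda i: (row_of[i], cents[i, 1]))
    labels = np.zeros_like(raw_labels)
    new_counts = np.zeros(len(keep) + 1, dtype=int)
    new_cents = np.zeros((len(keep) + 1, 2))
    new_rows = np.zeros(len(keep) + 1, dtype=int)
    new_pos = np.zeros(len(keep) + 1, dtype=int)
    pos_counter: dict[int, int] = {}
    for new_id, i in enumerate(reading, start=1):
        labels[raw_labels == keep[i]] = new_id
        new_counts[new_id] = counts[keep[i]]
        new_cents[new_id] = cents[i]
        r = int(row_of[i])
        new_rows[new_id] = r
        new_pos[new_id] = pos_counter.get(r, 0)
        pos_counter[r] = new_pos[new_id] + 1
    return LabelMap(labels=labels, counts=new_counts, centroids=new_cents,
                    rows=new_rows, positions=new_pos, dropped=dropped)


def extract_mean_spectra(cube: Hypercube, label_map: LabelMap,
                         metadata: pd.DataFrame | None = None) -> SpectraTable:
    """Unweighted per-kernel mean spectrum at every band.

    ``metadata`` (optional) is joined on the (row, position) tray index and
    may provide columns id/batch/orientation/hardness/protein_ref/weight_ref.
    """
    k = label_map.n_kernels
    spectra = np.empty((k, cube.n_bands))
    flat_labels = label_map.labels.ravel()
    flat_data = cube.data.reshape(-1, cube.n_bands).astype(np.float64)
    for label in range(1, k + 1):
        idx = np.flatnonzero(flat_labels == label)
        assert idx.size > 0, "labelled region with zero pixels"
        spectra[label - 1] = flat_data[idx].mean(axis=0)

    meta_lookup = {}
    if metadata is not None:
        for _, m in metadata.iterrows():
            meta_lookup[(int(m["row"]), int(m["position"]))] = m
    records = []
    for label in range(1, k + 1):
        key = (int(label_map.rows[label]), int(label_map.positions[label]))
        m = meta_lookup.get(key)
        records.append(KernelRecord(
            kernel_id=int(m["kernel"]) if m is not None else label,
            batch=int(m["batch"]) if m is not None else 0,
            row=key[0], position=key[1],
            orientation=m["orientation"] if m is not None else "unknown",
            hardness=m.get("hardness") if m is not None else None,
            area_px=int(label_map.counts[label]),
            pixel_size_mm=cube.pixel_size_mm,
            protein_ref=float(m["protein_ref"]) if m is not None else None,
            weight_ref=float(m["weight_ref"]) if m is not None else None,
        ))
    return SpectraTable(spectra, cube.grid, records)
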