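"""Per-pixel protein mapping and kernel/batch aggregation.

A saved calibration is applied to every labelled pixel's spectrum (with the
model's frozen pretreatment chain re-applied per pixel), producing a protein
map defined only on kernel pixels.  Kernel and batch values can be aggregated
either as the mean of pixel predictions (``pixel_mean``) or as the prediction
of the kernel-mean spectrum (``spectrum_mean``); the two coincide exactly for
linear pretreatments and are both reported when they differ (SNV/MSC act
per-spectrum and do not commute with averaging).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .hypercube import Hypercube
from .pipeline import LabelMap, SpectraTable, extract_mean_spectra

__all__ = [
    "ProteinMap",
    "predict_pixels",
    "aggregate",
    "aggregate_table",
    "area_weight_stats",
    "render_map",
]


@dataclass
class ProteinMap:
    """Per-pixel predicted protein (% as-is), NaN outside labelled kernels."""

    values: np.ndarray
    provenance: dict = field(default_factory=dict)
    n_out_of_range: int = 0

    def __post_init__(self):
        if np.any(~np.isfinite(self.values) & ~np.isnan(self.values)):
            raise ValueError("protein map must be finite where defined")


def predict_pixels(cube: Hypercube, label_map: LabelMap, model) -> ProteinMap:
    """Score every labelled pixel with a fitted calibration.

    ``model`` is a PLSCalibrationResults or FrozenCalibration: anything with
    ``predict(spectra, grid)`` applying its frozen pretreatment.  Out-of-range
    predictions (< 0 or > 100 %) are kept and counted, not clipped —
    clipping happens only at render time.
    """
    if cube.stage != "absorbance":
        raise ValueError(f"expected absorbance cube, got {cube.stage!r}")
    values = np.full(cube.data.shape[:2], np.nan)
    mask = label_map.labels > 0
    if mask.any():
        spectra = cube.data[mask].astype(np.float64)
        values[mask] = model.predict(spectra, cube.grid)
    n_oor = int(np.sum((values < 0) | (values > 100)))
    return ProteinMap(values=values, provenance={
        "n_components": getattr(model, "n_components", None),
        "pretreatment": repr(getattr(model, "pretreatment",
                                     getattr(getattr(model, "model", None),
                                             "pretreatment", None))),
    }, n_out_of_range=n_oor)


def aggregate(label_map: LabelMap, *, protein_map: ProteinMap | None = None,
              cube: Hypercube | None = None, model=None,
              metadata: pd.DataFrame | None = None, level: str = "kernel",
              mode: str = "pixel_mean") -> pd.DataFrame:
    """Kernel- or batch-level protein summaries from a map or cube.

    ``pixel_mean`` averages the per-pixel predictions of ``protein_map``;
    ``spectrum_mean`` predicts on each kernel's mean spectrum from ``cube``
    (requires ``model``).  Batch values are unweighted means of kernel values.
    """
    if level not in ("kernel", "batch"):
        raise ValueError(f"unknown aggregation level {level!r}")
    k = label_map.n_kernels
    if mode == "pixel_mean":
        if protein_map is None:
            raise ValueError("pixel_mean aggregation needs a protein map")
        vals = np.array([
            np.nanmean(protein_map.values[label_map.labels == label])
            for label in range(1, k + 1)])
    elif mode == "spectrum_mean":
        if cube is None or model is None:
            raise ValueError("spectrum_mean aggregation needs cube and model")
        table = extract_mean_spectra(cube, label_map, metadata)
        vals = model.predict(table.spectra, table.grid)
    else:
        raise ValueError(f"unknown aggregation mode {mode!r}")

    out = pd.DataFrame({
        "label": np.arange(1, k + 1),
        "row": label_map.rows[1:k + 1],
        "position": label_map.positions[1:k + 1],
        "predicted": vals,
        "mode": mode,
    })
    if metadata is not None:
        meta = metadata.set_index(["row", "position"])
        joined = out.join(meta, on=["row", "position"], rsuffix="_meta")
        for col in ("batch", "kernel", "protein_ref", "protein_true"):
            if col in joined:
                out[col] = joined[col].to_numpy()
    if level == "batch":
        group = out["batch"] if "batch" in out else pd.Series(0, index=out.index)
        agg = out.groupby(group)["predicted"].mean().rename("predicted").reset_index()
        agg["mode"] = mode
        return agg
    return out


def aggregate_table(table: SpectraTable, model, level: str = "batch"
                    ) -> pd.DataFrame:
    """Spectrum-mean aggregation straight from a kernel-mean spectra table."""
    pred = model.predict(table.spectra, table.grid)
    meta = table.metadata()
    meta["predicted"] = pred
    if level == "kernel":
        return meta[["id", "batch", "predicted"]]
    return meta.groupby("batch", as_index=False)["predicted"].mean()


@dataclass
class AreaWeightStats:
    r_area_weight: float
    p_area_weight: float
    r_weight_protein: float
    p_weight_protein: float
    area_fit_rmse_mm2: float
    n: int

    def as_dict(self) -> dict:
        return {"r_area_weight": self.r_area_weight,
                "p_area_weight": self.p_area_weight,
                "r_weight_protein": self.r_weight_protein,
                "p_weight_protein": self.p_weight_protein,
                "area_fit_rmse_mm2": self.area_fit_rmse_mm2, "n": self.n}


def area_weight_stats(records) -> AreaWeightStats:
    """Pearson correlations area-weight and weight-protein, plus the RMS of
    projected area about its linear regression on weight (mm^2).

    p-values use the two-sided t approximation and are approximate.
    Accepts a list of KernelRecords or a DataFrame with columns
    area_mm2 / weight_ref / protein_ref.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame([{"area_mm2": r.area_mm2, "weight_ref": r.weight_ref,
                            "protein_ref": r.protein_ref} for r in records])
    df = df.dropna(subset=["area_mm2", "weight_ref"])
    if len(df) < 3:
        raise ValueError("need at least 3 records with area and weight")
    area = df["area_mm2"].to_numpy(dtype=float)
    weight = df["weight_ref"].to_numpy(dtype=float)
    for name, v in (("area", area), ("weight", weight)):
        if np.var(v) < 1e-24:
            raise ValueError(f"zero variance in {name}")
    r_aw, p_aw = stats.pearsonr(area, weight)
    slope, intercept = np.polyfit(weight, area, 1)
    rms = float(np.sqrt(np.mean((area - (slope * weight + intercept)) ** 2)))
    if "protein_ref" in df and df["protein_ref"].notna().all():
        protein = df["protein_ref"].to_numpy(dtype=float)
        if np.var(protein) < 1e-24:
            raise ValueError("zero variance in protein")
        r_wp, p_wp = stats.pearsonr(weight, protein)
    else:
        r_wp, p_wp = np.nan, np.nan
    return AreaWeightStats(float(r_aw), float(p_aw), float(r_wp), float(p_wp),
                           rms, len(df))


def render_map(protein_map: ProteinMap, label_map: LabelMap, path, *,
               annotations: pd.DataFrame | None = None,
               vmin: float = 5.0, vmax: float = 20.0) -> None:
    """False-colour PNG of the protein map with optional per-kernel overlays.

    Values are clipped to [vmin, vmax] for display only.  Output bytes are
    deterministic for fixed input and colour scale.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4), dpi=120)
    shown = np.clip(protein_map.values, vmin, vmax)
    im = ax.imshow(shown, cmap="viridis", vmin=vmin, vmax=vmax,
                   interpolation="nearest")
    ax.set_facecolor("black")
    fig.colorbar(im, ax=ax, label="protein (% as-is)")
    if annotations is not None:
        for _, a in annotations.iterrows():
            label = int(a["label"])
            cl, cs = label_map.centroids[label]
            text = f"{a['predicted']:.1f}"
            if "protein_ref" in a and pd.notna(a.get("protein_ref")):
                text += f"\n({a['protein_ref']:.1f})"
            ax.text(cs, cl, text, color="white", ha="center", va="center",
                    fontsize=6)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
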