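"""Synthetic push-broom scenes of single wheat kernels on an NIR-absorbent tray.

The simulator emulates the statistical structure a single-kernel protein
calibration study rests on: ~10-12 kernels per batch laid out in two rows,
each kernel scanned crease-up and crease-down, protein drawn from a truncated
normal (mean 10.59 %, SD 2.07 %, range 6.15-19.77 % "as-is"), kernel weight
coupled to projected area (Pearson r near 0.88) but essentially independent
of protein.  Kernel optics follow a diagonal Beer-Lambert model: per-pixel
absorbance is an effective pathlength times a composition-weighted sum of
component absorptivity curves (protein, starch, water), each a sum of
Gaussian bands.  Raw counts are produced by inverting the reflectance
calibration (black + (white-black) * 10**-A) and adding detector noise,
multiplicative/additive scatter and registered single-pixel spikes, so the
full downstream pipeline is testable against exact ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .hypercube import Hypercube, ReferencePair, WavelengthGrid
from .pipeline import KernelRecord, SpectraTable

__all__ = [
    "TruncatedNormal",
    "OpticsConfig",
    "LayoutConfig",
    "SceneConfig",
    "ComponentLibrary",
    "SceneTruth",
    "generate_component_spectra",
    "default_component_library",
    "sample_kernel_population",
    "render_scene",
    "simulate_spectra_table",
    "noise_floor",
]

ORIENTATIONS = ("crease_up", "crease_down")

# mg / mm^3 scale of the weight = density * area^(3/2) coupling; fixed so the
# default area distribution reproduces a ~49.6 mg mean weight.
_KERNEL_DENSITY = 0.248


@dataclass(frozen=True)
class TruncatedNormal:
    """Normal(mean, sd) restricted to [lo, hi] by rejection sampling."""

    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if not self.lo < self.hi:
            raise ValueError("need lo < hi")
        if not (self.lo <= self.mean <= self.hi):
            raise ValueError("mean outside truncation bounds")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        out = np.empty(n)
        filled = 0
        while filled < n:
            draw = rng.normal(self.mean, self.sd, size=max(n - filled, 16))
            keep = draw[(draw >= self.lo) & (draw <= self.hi)]
            take = min(keep.size, n - filled)
            out[filled:filled + take] = keep[:take]
            filled += take
        return out


@dataclass
class OpticsConfig:
    """Imager geometry, radiometry and artifact rates."""

    n_bands: int = 256
    lambda_min_nm: float = 980.0
    lambda_max_nm: float = 2500.0
    pixel_size_mm: float = 0.109
    white_level: float = 40000.0     # counts at the PTFE panel
    black_level: float = 1000.0      # dark-current counts
    noise_sd: float = 80.0           # per-pixel Gaussian count noise
    n_reference_frames: int = 100    # frames averaged into each reference
    scatter_mult_range: float = 0.05  # multiplicative scatter amplitude (+-)
    scatter_add_range: float = 0.02   # additive absorbance scatter amplitude (+-)
    scatter_corr_px: float = 5.0      # spatial correlation length of scatter
    spike_rate: float = 2e-6          # fraction of (line, sample, band) cells spiked
    spike_magnitude: tuple[float, float] = (0.6, 1.5)  # |dA| range of a spike

    def __post_init__(self):
        if self.n_bands < 2:
            raise ValueError("need at least 2 bands")
        if not 0 <= self.spike_rate <= 1:
            raise ValueError("spike rate must be in [0, 1]")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel size must be positive")
        if self.white_level <= self.black_level:
            raise ValueError("white level must exceed black level")

    def wavelength_grid(self) -> WavelengthGrid:
        return WavelengthGrid(
            np.linspace(self.lambda_min_nm, self.lambda_max_nm, self.n_bands)
        )


@dataclass
class LayoutConfig:
    """Two-row tray layout; distances in mm."""

    n_rows: int = 2
    kernel_pitch_mm: float = 7.0   # centre spacing along a row (sample axis)
    row_pitch_mm: float = 14.0     # row spacing (line / scan axis)
    margin_mm: float = 2.5
    tray_width_mm: float = 55.0

    def __post_init__(self):
        if self.n_rows < 1:
            raise ValueError("need at least one row")
        if min(self.kernel_pitch_mm, self.row_pitch_mm, self.margin_mm) <= 0:
            raise ValueError("layout distances must be positive")


@dataclass
class SceneConfig:
    """Full study conditions for a simulated single-kernel experiment."""

    n_batches: int = 1
    kernels_per_batch: int = 11
    orientations: tuple[str, ...] = ORIENTATIONS
    protein_dist: TruncatedNormal = field(
        default_factory=lambda: TruncatedNormal(10.59, 2.07, 6.15, 19.77))
    weight_dist: TruncatedNormal = field(
        default_factory=lambda: TruncatedNormal(49.6, 12.0, 15.5, 87.7))
    area_dist: TruncatedNormal = field(
        default_factory=lambda: TruncatedNormal(33.79, 5.54, 18.0, 52.0))
    aspect_dist: TruncatedNormal = field(
        default_factory=lambda: TruncatedNormal(2.0, 0.15, 1.6, 2.4))
    moisture_dist: TruncatedNormal = field(
        default_factory=lambda: TruncatedNormal(0.12, 0.010, 0.08, 0.16))
    protein_ref_sd: float = 0.40     # reference (Dumas) repeatability, % protein
    structure_sd: float = 0.004      # smooth unmodelled spectral variability (AU)
    structure_corr_nm: float = 60.0  # correlation length of that variability
    weight_ref_sd: float = 0.5       # balance repeatability, mg
    weight_area_noise_sd: float = 0.13  # lognormal sd of the weight-area residual
    orientation_effect_sd: float = 0.01  # multiplicative crease-up/down shift
    protein_ramp: float = 0.0        # optional linear protein gradient along kernel
    edge_blend_px: float = 2.5       # penumbra width at kernel/tray boundary
    hard_fraction: float = 0.6       # fraction of batches labelled hard wheat
    seed: int = 0
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    layout: LayoutConfig = field(default_factory=LayoutConfig)

    def __post_init__(self):
        if self.n_batches < 0 or self.kernels_per_batch < 0:
            raise ValueError("counts must be >= 0")
        for o in self.orientations:
            if o not in ORIENTATIONS:
                raise ValueError(f"unknown orientation {o!r}")

    # -- JSON round-trip -------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SceneConfig":
        raw = json.loads(text)
        for key in ("protein_dist", "weight_dist", "area_dist", "aspect_dist",
                    "moisture_dist"):
            raw[key] = TruncatedNormal(**raw[key])
        raw["optics"] = OpticsConfig(**{**raw["optics"], "spike_magnitude":
                                        tuple(raw["optics"]["spike_magnitude"])})
        raw["layout"] = LayoutConfig(**raw["layout"])
        raw["orientations"] = tuple(raw["orientations"])
        return cls(**raw)


@dataclass
class ComponentLibrary:
    """Per-component absorptivity curves on a common wavelength grid.

    Each curve is a baseline plus a sum of Gaussian bands
    amp * exp(-(lambda - centre)^2 / (2 width^2)).
    """

    grid: WavelengthGrid
    curves: dict[str, np.ndarray]
    bands: dict[str, list[tuple[float, float, float]]]
    baselines: dict[str, float]

    def __post_init__(self):
        for name, curve in self.curves.items():
            if np.any(curve < 0):
                raise ValueError(f"component {name!r} has negative absorptivity")


def _structure_spectra(config: SceneConfig, grid: WavelengthGrid, n: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Smooth per-spectrum unmodelled variability, pointwise sd ~ structure_sd.

    Random coefficients on a coarse Gaussian-bump basis: emulates the
    biochemical and physical kernel-to-kernel variation a three-component
    mixture model does not capture.
    """
    if config.structure_sd <= 0:
        return np.zeros((n, len(grid)))
    width = config.structure_corr_nm
    centres = np.arange(grid.values[0] - width,
                        grid.values[-1] + width, width * 1.3)
    basis = np.exp(-((grid.values[None, :] - centres[:, None]) ** 2)
                   / (2 * width ** 2))
    z = rng.standard_normal((n, centres.size))
    raw = z @ basis
    scale = np.sqrt(np.mean(np.sum(basis ** 2, axis=0)))
    return raw * (config.structure_sd / scale)


@dataclass
class SceneTruth:
    """Ground truth and planted-artifact registry for a simulated study.

    ``kernels`` has one row per kernel-orientation; ``spikes`` one row per
    planted spike; ``true_mean_spectra`` maps (batch, orientation) to the
    (kernels, bands) noise-free kernel-mean absorbance of a rendered image.
    """

    kernels: pd.DataFrame
    library: ComponentLibrary
    config: SceneConfig
    spikes: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["batch", "orientation", "line", "sample", "band",
                 "clean_raw", "clean_absorbance", "spiked_absorbance",
                 "noise_sd_absorbance"]))
    true_mean_spectra: dict = field(default_factory=dict)
    nominal_noise_sd: dict = field(default_factory=dict)
    structure: np.ndarray | None = None  # per kernel-orientation row, (N, B)

    def image_rows(self, batch: int, orientation: str) -> pd.DataFrame:
        sel = (self.kernels["batch"] == batch) & \
              (self.kernels["orientation"] == orientation)
        return self.kernels.loc[sel].sort_values(["row", "position"])


# ---------------------------------------------------------------------------
# Component spectra


def generate_component_spectra(
    grid: WavelengthGrid,
    bands: Mapping[str, list[tuple[float, float, float]]],
    baselines: Mapping[str, float] | None = None,
) -> ComponentLibrary:
    """Evaluate each component's Gaussian band set on the grid.

    Deterministic; raises on a non-increasing grid (enforced by
    WavelengthGrid) or an empty band list for a named component.
    """
    baselines = dict(baselines or {})
    curves: dict[str, np.ndarray] = {}
    for name, blist in bands.items():
        if len(blist) == 0:
            raise ValueError(f"component {name!r} has an empty band list")
        curve = np.full(len(grid), float(baselines.get(name, 0.0)))
        for centre, width, amp in blist:
            if width <= 0:
                raise ValueError(f"non-positive band width in component {name!r}")
            curve = curve + amp * np.exp(
                -((grid.values - centre) ** 2) / (2.0 * width ** 2))
        curves[name] = curve
    return ComponentLibrary(grid=grid, curves=curves, bands={k: list(v) for k, v
                                                             in bands.items()},
                            baselines=baselines)


# Protein combination/overtone bands sit at 1918, 2008, 2062 and 2272 nm
# (amide C=O second overtone and N-H combinations) plus a weaker N-H overtone
# near 1500 nm; moisture at 1450 and 1936 nm (O-H combination); carbohydrate
# C-H bands at 1200/1580/2100/2320 nm.  The tray is an NIR-absorbent plastic
# with a broad resonance covering 1186 nm.
DEFAULT_COMPONENT_BANDS: dict[str, list[tuple[float, float, float]]] = {
    "protein": [(1500.0, 40.0, 0.12), (1918.0, 28.0, 1.80), (2008.0, 20.0, 0.90),
                (2062.0, 20.0, 1.30), (2272.0, 30.0, 1.00)],
    "water": [(1450.0, 40.0, 1.20), (1936.0, 28.0, 1.40)],
    "starch": [(1200.0, 60.0, 0.15), (1580.0, 60.0, 0.30), (2100.0, 45.0, 0.70),
               (2320.0, 45.0, 0.50)],
    "tray": [(1186.0, 55.0, 0.65)],
}
DEFAULT_COMPONENT_BASELINES = {"protein": 0.30, "water": 0.30, "starch": 0.28,
                               "tray": 0.75}


def default_component_library(grid: WavelengthGrid) -> ComponentLibrary:
    return generate_component_spectra(grid, DEFAULT_COMPONENT_BANDS,
                                      DEFAULT_COMPONENT_BASELINES)


def _kernel_mixture(lib: ComponentLibrary, protein_pct: float,
                    moisture: float) -> np.ndarray:
    """Composition-weighted absorptivity of a kernel (unit pathlength)."""
    p = protein_pct / 100.0
    s = 1.0 - p - moisture
    return (p * lib.curves["protein"] + moisture * lib.curves["water"]
            + s * lib.curves["starch"])


# ---------------------------------------------------------------------------
# Population sampling


def sample_kernel_population(config: SceneConfig,
                             library: ComponentLibrary | None = None) -> SceneTruth:
    """Draw the kernel population and tray layout; no images yet.

    Reproducible for a given config seed.  Both orientations of a kernel share
    all truth values except the orientation-specific scatter factor.
    """
    rng = np.random.default_rng(config.seed)
    grid = config.optics.wavelength_grid()
    if library is None:
        library = default_component_library(grid)

    layout = config.layout
    px = config.optics.pixel_size_mm
    per_row = int(np.ceil(config.kernels_per_batch / layout.n_rows)) \
        if config.kernels_per_batch else 0
    if per_row:
        needed = 2 * layout.margin_mm + per_row * layout.kernel_pitch_mm
        if needed > layout.tray_width_mm:
            raise ValueError(
                f"layout overflow: {per_row} kernels per row need "
                f"{needed:.1f} mm but the tray is {layout.tray_width_mm} mm wide")

    n = config.n_batches * config.kernels_per_batch
    protein = config.protein_dist.sample(rng, n)
    area = config.area_dist.sample(rng, n)
    aspect = config.aspect_dist.sample(rng, n)
    moisture = config.moisture_dist.sample(rng, n)
    eps = np.clip(rng.normal(0.0, config.weight_area_noise_sd, n),
                  -2.5 * config.weight_area_noise_sd,
                  2.5 * config.weight_area_noise_sd)
    weight = _KERNEL_DENSITY * area ** 1.5 * np.exp(eps)
    # effective optical thickness: taller kernels absorb more; normalised so
    # the population mean is ~1
    thickness = np.sqrt(area / config.area_dist.mean) * np.exp(eps)
    protein_ref = protein + rng.normal(0.0, config.protein_ref_sd, n)
    weight_ref = weight + rng.normal(0.0, config.weight_ref_sd, n)
    hardness_by_batch = np.where(
        rng.random(config.n_batches) < config.hard_fraction, "hard", "soft")

    rows = []
    for i in range(n):
        batch = i // config.kernels_per_batch if config.kernels_per_batch else 0
        within = i % config.kernels_per_batch if config.kernels_per_batch else 0
        row = within // per_row
        pos = within % per_row
        a_mm = np.sqrt(area[i] * aspect[i] / np.pi)   # semi-axis, scan direction
        b_mm = np.sqrt(area[i] / (np.pi * aspect[i]))
        centre_line = (layout.margin_mm + (row + 0.5) * layout.row_pitch_mm) / px
        centre_sample = (layout.margin_mm + (pos + 0.5) * layout.kernel_pitch_mm) / px
        for orientation in config.orientations:
            rows.append({
                "batch": batch, "kernel": i, "row": row, "position": pos,
                "orientation": orientation,
                "hardness": hardness_by_batch[batch],
                "protein_true": protein[i], "protein_ref": protein_ref[i],
                "weight_mg": weight[i], "weight_ref": weight_ref[i],
                "moisture": moisture[i],
                "area_mm2_true": area[i], "aspect": aspect[i],
                "a_px": a_mm / px, "b_px": b_mm / px,
                "area_px_true": area[i] / px ** 2,
                "centre_line": centre_line, "centre_sample": centre_sample,
                "thickness": thickness[i],
                "orientation_factor": float(np.clip(
                    rng.normal(1.0, config.orientation_effect_sd),
                    1 - 3 * config.orientation_effect_sd,
                    1 + 3 * config.orientation_effect_sd)),
            })
    kernels = pd.DataFrame(rows, columns=[
        "batch", "kernel", "row", "position", "orientation", "hardness",
        "protein_true", "protein_ref", "weight_mg", "weight_ref", "moisture",
        "area_mm2_true", "aspect", "a_px", "b_px", "area_px_true",
        "centre_line", "centre_sample", "thickness", "orientation_factor"])
    structure = _structure_spectra(config, grid, len(kernels), rng)
    return SceneTruth(kernels=kernels, library=library, config=config,
                      structure=structure)


# ---------------------------------------------------------------------------
# Rendering


def _image_shape(config: SceneConfig) -> tuple[int, int]:
    layout, px = config.layout, config.optics.pixel_size_mm
    per_row = int(np.ceil(config.kernels_per_batch / layout.n_rows)) \
        if config.kernels_per_batch else 1
    n_lines = int(round((2 * layout.margin_mm
                         + layout.n_rows * layout.row_pitch_mm) / px))
    n_samples = int(round((2 * layout.margin_mm
                           + per_row * layout.kernel_pitch_mm) / px))
    return n_lines, n_samples


def _reference_frames(config: SceneConfig, n_samples: int,
                      rng: np.random.Generator) -> ReferencePair:
    opt = config.optics
    b = np.arange(opt.n_bands)
    envelope = 0.75 + 0.25 * np.cos((b - opt.n_bands / 2) / opt.n_bands * np.pi)
    col_gain = 1.0 + 0.01 * np.sin(np.linspace(0, 3 * np.pi, n_samples))
    white = opt.white_level * col_gain[:, None] * envelope[None, :]
    black = np.full((n_samples, opt.n_bands), opt.black_level)
    ref_noise = opt.noise_sd / np.sqrt(opt.n_reference_frames)
    if ref_noise > 0:
        white = white + rng.normal(0.0, ref_noise, white.shape)
        black = black + rng.normal(0.0, ref_noise, black.shape)
    return ReferencePair(black=black, white=white,
                         n_black_frames=opt.n_reference_frames,
                         n_white_frames=opt.n_reference_frames)


def render_scene(truth: SceneTruth, config: SceneConfig | None = None, *,
                 batch: int = 0, orientation: str = "crease_up",
                 rng: np.random.Generator | None = None,
                 ) -> tuple[Hypercube, ReferencePair, SceneTruth]:
    """Render one tray image (one batch, one orientation) to raw counts.

    Per kernel pixel the clean absorbance is
    ``pathlength * thickness * orientation_factor * sum_i c_i k_i(lambda)``
    blended smoothly into the tray spectrum over ``edge_blend_px`` at the
    boundary; per-pixel multiplicative and additive scatter follow; raw
    counts are ``black + (white - black) * 10**-A`` plus Gaussian count noise;
    planted single-(pixel, band) spikes are registered in the truth.
    """
    if config is None:
        config = truth.config
    opt = config.optics
    grid = truth.library.grid
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 7919, batch,
                                    ORIENTATIONS.index(orientation)]))
    n_lines, n_samples = _image_shape(config)
    n_bands = opt.n_bands

    refs = _reference_frames(config, n_samples, rng)
    refs.validate()

    tray = truth.library.curves["tray"]
    clean = np.broadcast_to(tray.astype(np.float32),
                            (n_lines, n_samples, n_bands)).copy()

    rows = truth.image_rows(batch, orientation)
    seg_band = grid.nearest_band(1186.0)
    mean_spectra = np.zeros((len(rows), n_bands))
    area_seg = np.zeros(len(rows), dtype=int)
    for j, (_, k) in enumerate(rows.iterrows()):
        a, bax = k["a_px"], k["b_px"]
        cl, cs = k["centre_line"], k["centre_sample"]
        lo_l = max(int(cl - a - 4 * config.edge_blend_px), 0)
        hi_l = min(int(cl + a + 4 * config.edge_blend_px) + 1, n_lines)
        lo_s = max(int(cs - bax - 4 * config.edge_blend_px), 0)
        hi_s = min(int(cs + bax + 4 * config.edge_blend_px) + 1, n_samples)
        ll, ss = np.meshgrid(np.arange(lo_l, hi_l), np.arange(lo_s, hi_s),
                             indexing="ij")
        r = np.sqrt(((ll - cl) / a) ** 2 + ((ss - cs) / bax) ** 2)
        blend_r = config.edge_blend_px / bax  # penumbra in normalised radius
        mix = 1.0 / (1.0 + np.exp((r - 1.0) / max(blend_r / 2, 1e-9)))
        path = (0.7 + 0.3 * (1.0 - np.minimum(r, 1.0) ** 2)) / 0.85
        if config.protein_ramp:
            p_local = k["protein_true"] * (
                1.0 + config.protein_ramp * (ll - cl) / a)
        else:
            p_local = np.full(ll.shape, k["protein_true"])
        mixture = (p_local[..., None] / 100.0 * truth.library.curves["protein"]
                   + k["moisture"] * truth.library.curves["water"]
                   + (1.0 - p_local[..., None] / 100.0 - k["moisture"])
                   * truth.library.curves["starch"])
        if truth.structure is not None:
            # truth.kernels carries a RangeIndex, so the row label indexes
            # the aligned structure array directly
            mixture = mixture + truth.structure[int(_)]
        a_kernel = (path * k["thickness"] * k["orientation_factor"])[..., None] \
            * mixture
        patch = mix[..., None] * a_kernel + (1 - mix[..., None]) * tray
        clean[lo_l:hi_l, lo_s:hi_s, :] = patch.astype(np.float32)
        # truth support = the segmentable pixel set of the clean image, so a
        # perfect pipeline recovers these means exactly
        support = patch[..., seg_band] < 0.9
        mean_spectra[j] = patch[support].mean(axis=0)
        area_seg[j] = int(support.sum())

    # scatter: one multiplicative and one additive field per pixel, common to
    # all bands and spatially smooth (physical scatter varies at kernel
    # scale, not pixel scale)
    def _smooth_field(amplitude: float) -> np.ndarray:
        if amplitude <= 0:
            return np.zeros((n_lines, n_samples))
        from scipy.ndimage import gaussian_filter
        field = rng.standard_normal((n_lines, n_samples))
        field = gaussian_filter(field, opt.scatter_corr_px, mode="reflect")
        field /= max(field.std(), 1e-12)
        return np.clip(field * amplitude / np.sqrt(3.0),
                       -amplitude, amplitude)

    mult = 1.0 + _smooth_field(opt.scatter_mult_range)
    add = _smooth_field(opt.scatter_add_range)
    absorb = clean * mult[..., None].astype(np.float32) \
        + add[..., None].astype(np.float32)

    signal = refs.white - refs.black  # (S, B)
    raw = refs.black[None].astype(np.float32) \
        + signal[None].astype(np.float32) * np.power(10.0, -absorb,
                                                     dtype=np.float32)

    # nominal noise scale: absorbance-equivalent count noise at the median
    # image radiance (used as the scene's single noise figure)
    median_counts = float(np.median(raw - refs.black[None]))
    nominal_sd = opt.noise_sd / (np.log(10.0) * max(median_counts, 1.0))

    # planted spikes (registered before noise; clean values are noise-free)
    n_cells = n_lines * n_samples * n_bands
    n_spikes = rng.binomial(n_cells, opt.spike_rate)
    spike_rows = []
    if n_spikes:
        flat = rng.choice(n_cells, size=n_spikes, replace=False)
        sl, ssmp, sb = np.unravel_index(flat, (n_lines, n_samples, n_bands))
        lo_m, hi_m = opt.spike_magnitude
        delta = rng.uniform(lo_m, hi_m, n_spikes) * rng.choice([-1.0, 1.0],
                                                               n_spikes)
        for i in range(n_spikes):
            l, s, b = int(sl[i]), int(ssmp[i]), int(sb[i])
            a_clean = absorb[l, s, b]
            a_spk = a_clean + delta[i]
            raw_spk = float(np.clip(refs.black[s, b]
                                    + signal[s, b] * 10.0 ** (-a_spk), 0, 65535))
            # absorbance the pipeline will actually see after inversion
            r_eff = (raw_spk - refs.black[s, b]) / signal[s, b]
            a_eff = -np.log10(max(r_eff, 1e-4))
            # absorbance-equivalent count noise at this pixel's clean
            # radiance, floored at the scene nominal figure
            local_sd = opt.noise_sd / (np.log(10.0)
                                       * max(raw[l, s, b] - refs.black[s, b],
                                             1.0))
            spike_rows.append({
                "batch": batch, "orientation": orientation,
                "line": l, "sample": s, "band": b,
                "clean_raw": float(raw[l, s, b]),
                "clean_absorbance": float(a_clean),
                "spiked_absorbance": float(a_eff),
                "noise_sd_absorbance": float(max(local_sd, nominal_sd)),
            })
            raw[l, s, b] = raw_spk
    if opt.noise_sd > 0:
        raw = raw + opt.noise_sd * rng.standard_normal(raw.shape,
                                                       dtype=np.float32)
        np.clip(raw, 0, None, out=raw)

    cube = Hypercube(raw, grid, "raw_counts", opt.pixel_size_mm)
    truth.true_mean_spectra[(batch, orientation)] = mean_spectra
    truth.nominal_noise_sd[(batch, orientation)] = nominal_sd
    key_rows = rows.index
    truth.kernels.loc[key_rows, "area_px_seg"] = area_seg
    new_spikes = pd.DataFrame(spike_rows, columns=truth.spikes.columns)
    truth.spikes = pd.concat([t for t in (truth.spikes, new_spikes)
                              if not t.empty], ignore_index=True) \
        if spike_rows else truth.spikes
    return cube, refs, truth


# ---------------------------------------------------------------------------
# Fast path: kernel-mean spectra without rendering full images


def _radial_kernel_mean(lib: ComponentLibrary, config: SceneConfig,
                        mixture: np.ndarray, thickness: float,
                        orient: float, b_px: float) -> np.ndarray:
    """Radial average of the rendered kernel profile over its segmentable
    support.

    The rendered patch depends on position only through the normalised
    radius r (pathlength dome and logistic edge blend), so its mean over the
    support set {A(1186 nm) < 0.9} equals this 1-D integral with weight
    r dr.  Reproduces the image pipeline's kernel means — including the
    partial tray contribution of edge pixels — without rendering.
    """
    tray = lib.curves["tray"]
    seg_band = lib.grid.nearest_band(1186.0)
    r = np.linspace(0.0, 1.5, 240)
    blend_r = config.edge_blend_px / b_px
    mix = 1.0 / (1.0 + np.exp((r - 1.0) / max(blend_r / 2, 1e-9)))
    path = (0.7 + 0.3 * (1.0 - np.minimum(r, 1.0) ** 2)) / 0.85
    amp = path * thickness * orient
    profile_seg = mix * amp * mixture[seg_band] + (1 - mix) * tray[seg_band]
    support = profile_seg < 0.9
    w = r * support
    spectra = (mix * amp)[:, None] * mixture[None, :] \
        + (1 - mix)[:, None] * tray[None, :]
    return (w @ spectra) / w.sum()


def simulate_spectra_table(config: SceneConfig,
                           library: ComponentLibrary | None = None,
                           truth: SceneTruth | None = None) -> tuple[SpectraTable,
                                                                     SceneTruth]:
    """Generate the kernel-mean SpectraTable directly.

    Statistically equivalent to rendering, calibrating, segmenting and
    averaging: the per-kernel mean absorbance is thickness * orientation
    factor * the Beer-Lambert mixture, plus the kernel-mean residual of the
    per-pixel scatter terms and band noise attenuated by the pixel count.
    Used for calibration-scale studies where full images would be wasteful.
    """
    if truth is None:
        truth = sample_kernel_population(config, library)
    lib = truth.library
    grid = lib.grid
    opt = config.optics
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 104729]))

    kern = truth.kernels
    n = len(kern)
    n_px = np.maximum(kern["area_px_true"].to_numpy(), 1.0)
    # residual kernel-mean scatter: the smooth scatter fields decorrelate over
    # ~pi * corr^2 pixels, so a kernel averages n_eff independent patches
    n_eff = np.maximum(n_px / (np.pi * opt.scatter_corr_px ** 2), 1.0)
    mult_resid = 1.0 + rng.normal(
        0.0, opt.scatter_mult_range / np.sqrt(3.0 * n_eff))
    add_resid = rng.normal(0.0, opt.scatter_add_range / np.sqrt(3.0 * n_eff))

    signal = opt.white_level - opt.black_level
    records, spectra = [], np.empty((n, len(grid)))
    for i, (_, k) in enumerate(kern.iterrows()):
        base = _kernel_mixture(lib, k["protein_true"], k["moisture"])
        if truth.structure is not None:
            base = base + truth.structure[int(_)]
        a = _radial_kernel_mean(lib, config, base, k["thickness"],
                                k["orientation_factor"], k["b_px"]) \
            * mult_resid[i] + add_resid[i]
        # count noise propagated to kernel-mean absorbance, band by band
        sd_band = opt.noise_sd / (np.log(10.0) * signal
                                  * np.power(10.0, -a)) / np.sqrt(n_px[i])
        a = a + rng.normal(0.0, 1.0, len(grid)) * sd_band
        spectra[i] = a
        records.append(KernelRecord(
            kernel_id=int(k["kernel"]), batch=int(k["batch"]),
            row=int(k["row"]), position=int(k["position"]),
            orientation=k["orientation"],
            area_px=int(round(k["area_px_true"])),
            pixel_size_mm=opt.pixel_size_mm,
            protein_ref=float(k["protein_ref"]),
            weight_ref=float(k["weight_ref"]),
            hardness=k["hardness"],
        ))
    table = SpectraTable(spectra=spectra, grid=grid, records=records)
    return table, truth


def noise_floor(config: SceneConfig) -> float:
    """Lower bound on achievable prediction RMSE, % protein.

    Dominated by the reference-method repeatability: validation references
    carry independent noise of sd ``protein_ref_sd``, so no calibration can
    beat that figure; spectral count noise on kernel means is orders of
    magnitude smaller at the default optics.
    """
    return config.protein_ref_sd
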