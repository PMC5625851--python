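"""NIPALS PLS1 calibration of kernel-mean NIR spectra.

The modelling surface follows the Model / Results convention: a
:class:`PLSCalibration` is built from a :class:`~grainspec.pipeline.SpectraTable`
(or raw arrays), its :meth:`~PLSCalibration.fit` performs the grain-level
80/20 split, fits the attached pretreatment chain on the calibration set,
selects the latent-variable count by grain-blocked cross-validation and runs
NIPALS on mean-centred data; the returned :class:`PLSCalibrationResults`
carries coefficients, the RMSECV curve, calibration/validation metrics
(slope, bias, RMSE, R^2, RPD), outlier diagnostics and a ``summary()`` table.

Grains — not spectra — are the sampling unit throughout: both orientations of
a kernel always land on the same side of every split and fold, so orientation
never leaks between calibration and validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hypercube import WavelengthGrid
from .pipeline import SpectraTable
from .pretreat import PretreatmentSpec

__all__ = [
    "SplitPlan",
    "CalibrationMetrics",
    "evaluate",
    "r2_from_rmse",
    "split_by_grain",
    "nipals_pls1",
    "select_ncomp",
    "PLSCalibration",
    "PLSCalibrationResults",
    "run_study",
    "DEFAULT_PROTEIN_SPECS",
    "DEFAULT_WEIGHT_SPECS",
]


# ---------------------------------------------------------------------------
# Splitting


@dataclass
class SplitPlan:
    """Grain-level calibration/validation assignment."""

    calibration_grains: np.ndarray
    validation_grains: np.ndarray
    fraction: float
    seed: int

    def masks(self, grain_ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cal = np.isin(grain_ids, self.calibration_grains)
        return cal, ~cal


def split_by_grain(grain_ids: np.ndarray, fraction: float = 0.8,
                   seed: int = 0) -> SplitPlan:
    """Sample grains (not spectra) without replacement into the calibration set."""
    grains = np.unique(np.asarray(grain_ids))
    if grains.size < 5:
        raise ValueError(f"need at least 5 grains, got {grains.size}")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n_cal = int(round(fraction * grains.size))
    cal = np.sort(rng.choice(grains, size=n_cal, replace=False))
    val = np.setdiff1d(grains, cal)
    if val.size == 0:
        import warnings
        warnings.warn("validation set is empty (fraction = 1)", stacklevel=2)
    return SplitPlan(cal, val, fraction, seed)


# ---------------------------------------------------------------------------
# Metrics


@dataclass
class CalibrationMetrics:
    """Slope / bias / RMSE / R^2 / RPD of predictions against references."""

    slope: float
    bias: float
    rmse: float
    r2: float
    rpd: float
    n: int
    n_components: int = 0

    def as_dict(self) -> dict:
        return {"slope": self.slope, "bias": self.bias, "rmse": self.rmse,
                "r2": self.r2, "rpd": self.rpd, "n": self.n,
                "pc": self.n_components}


def evaluate(predictions: np.ndarray, references: np.ndarray,
             n_components: int = 0) -> CalibrationMetrics:
    """Standard chemometric summary of a prediction set.

    bias = mean(pred - ref); rmse = sqrt(mean((pred - ref)^2)); slope is the
    least-squares slope of predictions regressed on references; R^2 =
    1 - SSE / SS_tot(ref); RPD = sample sd(ref) / rmse.
    """
    pred = np.asarray(predictions, dtype=float)
    ref = np.asarray(references, dtype=float)
    if pred.shape != ref.shape or pred.ndim != 1:
        raise ValueError("predictions and references must be aligned 1-D")
    n = pred.size
    if n < 2:
        raise ValueError("need at least 2 points")
    ss_tot = np.sum((ref - ref.mean()) ** 2)
    if ss_tot < 1e-24:
        raise ValueError("zero variance in references")
    resid = pred - ref
    bias = float(resid.mean())
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    slope = float(np.cov(ref, pred, ddof=1)[0, 1] / np.var(ref, ddof=1))
    r2 = float(1.0 - np.sum(resid ** 2) / ss_tot)
    sd = float(ref.std(ddof=1))
    rpd = float(sd / rmse) if rmse > 0 else float("inf")
    return CalibrationMetrics(slope, bias, rmse, r2, rpd, n, n_components)


def r2_from_rmse(rmse: float, sd: float) -> float:
    """R^2 implied by an RMSE and the reference standard deviation.

    The identity R^2 = 1 - (RMSE / SD)^2 ties the two error figures a model
    report prints; it is used to cross-check published tables for internal
    consistency.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    return 1.0 - (rmse / sd) ** 2


# ---------------------------------------------------------------------------
# NIPALS core


def nipals_pls1(X: np.ndarray, y: np.ndarray, n_components: int,
                *, allow_truncation: bool = False) -> dict:
    """NIPALS PLS1 on mean-centred data.

    Iterates w = X'y / ||X'y||, t = Xw, p = X't / t't, q = y't / t't, then
    deflates X <- X - t p' and y <- y - t q.  Returns weights W, loadings P,
    response loadings q, the collapsed coefficients beta = W (P'W)^-1 q and
    intercept beta0 = y_mean - x_mean' beta.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, b = X.shape
    if y.shape != (n,):
        raise ValueError("y must align with the rows of X")
    if not (1 <= n_components <= min(n - 1, b)):
        raise ValueError(f"n_components must be in [1, {min(n - 1, b)}]")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X and y must be finite")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    W = np.zeros((b, n_components))
    P = np.zeros((b, n_components))
    q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    achieved = n_components
    for a in range(n_components):
        cov = Xc.T @ yc
        norm = np.linalg.norm(cov)
        if norm < 1e-12 * max(1.0, np.abs(yc).max(initial=1.0)):
            if allow_truncation:
                achieved = a
                break
            raise ValueError(
                f"degenerate deflation at component {a + 1}: X carries no "
                "remaining covariance with y")
        w = cov / norm
        t = Xc @ w
        tt = float(t @ t)
        if tt < 1e-24:
            if allow_truncation:
                achieved = a
                break
            raise ValueError(f"zero-variance score at component {a + 1}")
        p = Xc.T @ t / tt
        q_a = float(yc @ t / tt)
        Xc = Xc - np.outer(t, p)
        yc = yc - t * q_a
        W[:, a], P[:, a], q[a], T[:, a] = w, p, q_a, t
    if achieved == 0:
        # y is (numerically) constant: the model is the mean
        return {"W": np.zeros((b, 0)), "P": np.zeros((b, 0)),
                "q": np.zeros(0), "T": np.zeros((n, 0)),
                "x_mean": x_mean, "y_mean": y_mean,
                "beta": np.zeros(b), "beta0": y_mean, "n_components": 0}
    W, P, q, T = W[:, :achieved], P[:, :achieved], q[:, None][:achieved, 0], \
        T[:, :achieved]
    beta = W @ np.linalg.solve(P.T @ W, q)
    beta0 = y_mean - x_mean @ beta
    return {"W": W, "P": P, "q": q, "T": T, "x_mean": x_mean,
            "y_mean": y_mean, "beta": beta, "beta0": float(beta0),
            "n_components": achieved}


def _scores(model: dict, X: np.ndarray) -> np.ndarray:
    """Latent scores of new data under a fitted NIPALS state."""
    Xc = np.asarray(X, dtype=np.float64) - model["x_mean"]
    A = model["n_components"]
    T = np.zeros((Xc.shape[0], A))
    for a in range(A):
        t = Xc @ model["W"][:, a]
        Xc = Xc - np.outer(t, model["P"][:, a])
        T[:, a] = t
    return T


def predict_scores(model: dict, X: np.ndarray) -> np.ndarray:
    """Score-form prediction y = y_mean + T q (equals the beta form)."""
    return model["y_mean"] + _scores(model, X) @ model["q"]


# ---------------------------------------------------------------------------
# Component selection


def _grain_folds(grain_ids: np.ndarray, folds: int, seed: int) -> list[np.ndarray]:
    grains = np.unique(grain_ids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(grains)
    groups = np.array_split(perm, folds)
    return [np.flatnonzero(np.isin(grain_ids, g)) for g in groups]


def select_ncomp(X: np.ndarray, y: np.ndarray, max_components: int = 20,
                 folds: int = 10, seed: int = 0,
                 grain_ids: np.ndarray | None = None
                 ) -> tuple[int, np.ndarray]:
    """Grain-blocked cross-validated latent-variable count.

    Returns (A*, RMSECV curve for A = 1..A_max); A* minimises RMSECV, ties
    within 1e-9 resolved to the smallest A (parsimony).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if grain_ids is None:
        grain_ids = np.arange(n)
    a_max = min(max_components, X.shape[1],
                n - int(np.ceil(n / folds)) - 1)
    if a_max < 1:
        raise ValueError("too few samples for cross-validation")
    fold_idx = _grain_folds(grain_ids, folds, seed)
    press = np.zeros(a_max)
    count = 0
    for test in fold_idx:
        if test.size == 0:
            continue
        train = np.setdiff1d(np.arange(n), test)
        if train.size < 2:
            raise ValueError("cross-validation fold leaves < 2 training samples")
        model = nipals_pls1(X[train], y[train],
                            min(a_max, train.size - 1, X.shape[1]),
                            allow_truncation=True)
        A = model["n_components"]
        T = _scores(model, X[test])
        cum = model["y_mean"] + np.cumsum(T * model["q"][None, :], axis=1)
        for a in range(a_max):
            pred = cum[:, min(a, A - 1)] if A else np.full(test.size,
                                                           model["y_mean"])
            press[a] += np.sum((pred - y[test]) ** 2)
        count += test.size
    rmsecv = np.sqrt(press / count)
    best = float(rmsecv.min())
    a_star = int(np.flatnonzero(rmsecv <= best + 1e-9)[0]) + 1
    return a_star, rmsecv


# ---------------------------------------------------------------------------
# Model / Results


class PLSCalibration:
    """PLS1 calibration model for a spectra table and one response.

    Parameters
    ----------
    table : SpectraTable
        Kernel-mean absorbance spectra with reference values.
    response : str
        "protein" (% as-is) or "weight" (mg).
    pretreatment : PretreatmentSpec, optional
        Chain applied before regression; fitted on the calibration subset.
    """

    def __init__(self, table: SpectraTable, response: str = "protein",
                 pretreatment: PretreatmentSpec | None = None):
        self.table = table
        self.response = response
        self.y = table.response(response)
        self.grain_ids = table.grain_ids()
        self.pretreatment = pretreatment or PretreatmentSpec([])

    @classmethod
    def from_table(cls, table: SpectraTable, response: str = "protein",
                   pretreatment: PretreatmentSpec | None = None
                   ) -> "PLSCalibration":
        return cls(table, response, pretreatment)

    def fit(self, n_components: int | None = None, max_components: int = 20,
            split_fraction: float = 0.8, cv_folds: int = 10, seed: int = 0
            ) -> "PLSCalibrationResults":
        plan = split_by_grain(self.grain_ids, split_fraction, seed)
        cal_mask, val_mask = plan.masks(self.grain_ids)
        cal_table = self.table.subset(cal_mask)
        self.pretreatment.fit(cal_table)
        Xc, grid = self.pretreatment.apply_matrix(cal_table.spectra,
                                                  cal_table.grid)
        y_cal = self.y[cal_mask]
        rmsecv = None
        if n_components is None:
            n_components, rmsecv = select_ncomp(
                Xc, y_cal, max_components, cv_folds, seed,
                grain_ids=self.grain_ids[cal_mask])
        state = nipals_pls1(Xc, y_cal, n_components, allow_truncation=True)
        return PLSCalibrationResults(self, state, plan, grid, rmsecv)


class PLSCalibrationResults:
    """Fitted calibration: coefficients, split, diagnostics and metrics."""

    def __init__(self, model: PLSCalibration, state: dict, plan: SplitPlan,
                 fitted_grid: WavelengthGrid, rmsecv: np.ndarray | None):
        self.model = model
        self.state = state
        self.plan = plan
        self.fitted_grid = fitted_grid
        self.rmsecv = rmsecv
        self.n_components = state["n_components"]
        self.beta = state["beta"]
        self.beta0 = state["beta0"]
        cal_mask, val_mask = plan.masks(model.grain_ids)
        self.cal_mask, self.val_mask = cal_mask, val_mask
        self.metrics_cal = evaluate(self.predict(model.table.subset(cal_mask)),
                                    model.y[cal_mask], self.n_components)
        self.metrics_val = None
        if val_mask.any():
            self.metrics_val = evaluate(
                self.predict(model.table.subset(val_mask)),
                model.y[val_mask], self.n_components)

    # -- prediction -------------------------------------------------------
    def transform(self, spectra: np.ndarray, grid: WavelengthGrid
                  ) -> np.ndarray:
        X, out_grid = self.model.pretreatment.apply_matrix(spectra, grid)
        if len(out_grid) != len(self.fitted_grid) or np.any(
                np.abs(out_grid.values - self.fitted_grid.values) > 1.0):
            raise ValueError("band centres differ from the training grid by "
                             "more than 1 nm")
        return X

    def predict(self, table_or_spectra, grid: WavelengthGrid | None = None
                ) -> np.ndarray:
        """Beta-form prediction of pretreated spectra."""
        if isinstance(table_or_spectra, SpectraTable):
            spectra, grid = table_or_spectra.spectra, table_or_spectra.grid
        else:
            spectra = np.asarray(table_or_spectra, dtype=float)
            if grid is None:
                raise ValueError("grid required for raw-array prediction")
        X = self.transform(np.atleast_2d(spectra), grid)
        return X @ self.beta + self.beta0

    def predict_via_scores(self, table: SpectraTable) -> np.ndarray:
        """Score-form prediction (cross-check of the collapsed coefficients)."""
        X = self.transform(table.spectra, table.grid)
        return predict_scores(self.state, X)

    # -- diagnostics ------------------------------------------------------
    def detect_outliers(self, leverage_k: float = 3.0, resid_k: float = 3.0
                        ) -> pd.DataFrame:
        """Leverage/residual screening of the calibration set.

        Leverage is the standard chemometric h = 1/N + sum_a t_a^2 / (t_a't_a);
        a sample is flagged when h exceeds leverage_k times the average
        leverage (A + 1)/N, or when its standardised residual exceeds
        resid_k in magnitude.  Flags are reported only; removal is the
        caller's explicit decision (at most one round).
        """
        T = self.state["T"]
        n, A = T.shape if T.size else (len(self.state["T"]), 0)
        cal = self.model.table.subset(self.cal_mask)
        y = self.model.y[self.cal_mask]
        resid = self.predict(cal) - y
        sd = resid.std(ddof=1) if n > 1 else 1.0
        std_resid = resid / (sd if sd > 0 else 1.0)
        if A:
            h = 1.0 / n + np.einsum(
                "ia,a,ia->i", T, 1.0 / np.einsum("ia,ia->a", T, T), T)
        else:
            h = np.full(n, 1.0 / n)
        lev_limit = leverage_k * ((A + 1) / n)
        return pd.DataFrame({
            "grain": self.model.grain_ids[self.cal_mask],
            "leverage": h, "std_residual": std_resid,
            "high_leverage": h > lev_limit,
            "high_residual": np.abs(std_resid) > resid_k,
            "flagged": (h > lev_limit) | (np.abs(std_resid) > resid_k),
        })

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "PLS1 calibration (NIPALS)",
            "=" * 60,
            f"response:        {self.model.response}",
            f"pretreatment:    {self.model.pretreatment!r}",
            f"latent variables: {self.n_components}",
            f"bands:           {len(self.fitted_grid)} "
            f"({self.fitted_grid.values[0]:.0f}-{self.fitted_grid.values[-1]:.0f} nm)",
            f"split:           {self.plan.calibration_grains.size} cal / "
            f"{self.plan.validation_grains.size} val grains "
            f"(fraction {self.plan.fraction}, seed {self.plan.seed})",
            "-" * 60,
            f"{'set':<12}{'n':>6}{'slope':>8}{'bias':>8}{'RMSE':>8}"
            f"{'R2':>8}{'RPD':>7}",
        ]
        for name, m in (("calibration", self.metrics_cal),
                        ("validation", self.metrics_val)):
            if m is None:
                lines.append(f"{name:<12}{'-':>6}")
                continue
            lines.append(f"{name:<12}{m.n:>6}{m.slope:>8.3f}{m.bias:>8.3f}"
                         f"{m.rmse:>8.3f}{m.r2:>8.3f}{m.rpd:>7.2f}")
        return "\n".join(lines)

    # -- persistence ------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "response": self.model.response,
            "n_components": self.n_components,
            "beta": self.beta.tolist(),
            "beta0": self.beta0,
            "x_mean": self.state["x_mean"].tolist(),
            "y_mean": self.state["y_mean"],
            "W": self.state["W"].tolist(),
            "P": self.state["P"].tolist(),
            "q": self.state["q"].tolist(),
            "pretreatment": json.loads(self.model.pretreatment.to_json()),
            "grid": self.fitted_grid.values.tolist(),
            "input_grid": self.model.table.grid.values.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "FrozenCalibration":
        return FrozenCalibration(json.loads(text))


class FrozenCalibration:
    """A saved calibration reloaded for prediction only."""

    def __init__(self, payload: dict):
        self.response = payload["response"]
        self.n_components = payload["n_components"]
        self.beta = np.asarray(payload["beta"])
        self.beta0 = float(payload["beta0"])
        self.pretreatment = PretreatmentSpec(payload["pretreatment"]["steps"],
                                             payload["pretreatment"].get("name"))
        self.fitted_grid = WavelengthGrid(np.asarray(payload["grid"]))
        self.input_grid = WavelengthGrid(np.asarray(payload["input_grid"]))

    def transform(self, spectra: np.ndarray, grid: WavelengthGrid) -> np.ndarray:
        X, out_grid = self.pretreatment.apply_matrix(spectra, grid)
        if len(out_grid) != len(self.fitted_grid) or np.any(
                np.abs(out_grid.values - self.fitted_grid.values) > 1.0):
            raise ValueError("band centres differ from the training grid by "
                             "more than 1 nm")
        return X

    def predict(self, spectra: np.ndarray, grid: WavelengthGrid) -> np.ndarray:
        X = self.transform(np.atleast_2d(spectra), grid)
        return X @ self.beta + self.beta0


# ---------------------------------------------------------------------------
# Study driver (published-table analog grids)


DEFAULT_PROTEIN_SPECS: list[PretreatmentSpec] = [
    PretreatmentSpec([], name="raw"),
    PretreatmentSpec([{"step": "normalise", "mode": "unit_area"}],
                     name="normalisation"),
    PretreatmentSpec([{"step": "msc", "reference": "training_mean"}], name="msc"),
    PretreatmentSpec([{"step": "snv"}], name="snv"),
    PretreatmentSpec([{"step": "snv"},
                      {"step": "savgol", "window": 5, "polyorder": 2,
                       "deriv": 1}], name="snv+1st_derivative"),
    PretreatmentSpec([{"step": "snv"}, {"step": "detrend", "order": 2}],
                     name="snv+detrend"),
    PretreatmentSpec([{"step": "savgol", "window": 5, "polyorder": 2,
                       "deriv": 2}], name="2nd_derivative"),
]

DEFAULT_WEIGHT_SPECS: list[PretreatmentSpec] = [
    PretreatmentSpec([], name="raw"),
    PretreatmentSpec([{"step": "baseline", "mode": "offset_min"},
                      {"step": "detrend", "order": 2}], name="baseline+detrend"),
    PretreatmentSpec([{"step": "msc", "reference": "training_mean"}], name="msc"),
    PretreatmentSpec([{"step": "snv"}], name="snv"),
    PretreatmentSpec([{"step": "snv"},
                      {"step": "savgol", "window": 5, "polyorder": 2,
                       "deriv": 1}], name="snv+1st_derivative"),
    PretreatmentSpec([{"step": "savgol", "window": 5, "polyorder": 2,
                       "deriv": 2}], name="2nd_derivative"),
]


def run_study(table: SpectraTable, response: str = "protein",
              specs: list[PretreatmentSpec] | None = None,
              wavelength_range: tuple[float, float] | None = (1060.0, 2494.0),
              subset: dict | None = None, split_fraction: float = 0.8,
              cv_folds: int = 10, max_components: int = 20, seed: int = 0
              ) -> tuple[pd.DataFrame, dict[str, PLSCalibrationResults]]:
    """Fit every pretreatment spec on one grain-level split; tabulate metrics.

    ``subset`` may filter by orientation and/or hardness before splitting;
    ``wavelength_range`` restricts the spectral window (applied before any
    pretreatment).  Returns the results grid (one row per spec, columns
    mirroring a calibration/validation performance table) and the fitted
    results keyed by spec name.
    """
    from .pretreat import restrict_range

    if specs is None:
        specs = DEFAULT_PROTEIN_SPECS if response == "protein" \
            else DEFAULT_WEIGHT_SPECS
    work = table
    if subset:
        meta = work.metadata()
        mask = np.ones(len(work), dtype=bool)
        for key, val in subset.items():
            mask &= (meta[key] == val).to_numpy()
        if not mask.any():
            raise ValueError(f"subset {subset} selects no spectra")
        work = work.subset(mask)
    if wavelength_range is not None:
        work = restrict_range(work, *wavelength_range)

    rows, fits = [], {}
    for spec in specs:
        spec = PretreatmentSpec([{k: v for k, v in s.items()
                                  if k != "frozen_reference"}
                                 for s in spec.steps], name=spec.name)
        res = PLSCalibration(work, response, spec).fit(
            max_components=max_components, split_fraction=split_fraction,
            cv_folds=cv_folds, seed=seed)
        m_cal, m_val = res.metrics_cal, res.metrics_val
        rows.append({
            "pretreatment": spec.name,
            "slope_cal": m_cal.slope, "bias_cal": m_cal.bias,
            "rmsec": m_cal.rmse, "r2_cal": m_cal.r2,
            "slope_val": m_val.slope if m_val else np.nan,
            "bias_val": m_val.bias if m_val else np.nan,
            "rmsep": m_val.rmse if m_val else np.nan,
            "r2_val": m_val.r2 if m_val else np.nan,
            "pc": res.n_components,
            "rpd": m_val.rpd if m_val else np.nan,
            "n_cal": m_cal.n, "n_val": m_val.n if m_val else 0,
        })
        fits[spec.name or str(len(fits))] = res
    return pd.DataFrame(rows), fits
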