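"""Classical drug-release kinetics: five dissolution models and their fits.

The models (all with time in hours, cumulative release Q in the curve's
declared units, released fraction f = Q / 100 on the percent scale):

==================  =====================================  ==================
model id            law                                    parameters
==================  =====================================  ==================
zero_order          Q_t = k0 * t                           k0
first_order         log10 Q_t = k * t / 2.303              k (+ Q0 intercept)
higuchi             Q_t = kH * sqrt(t)                     kH
korsmeyer_peppas    M_t / M_inf = k * t**n                 k, n (fraction)
hixson_crowell      W0**(1/3) - W_t**(1/3) = k * t         k (+ W0, dose)
==================  =====================================  ==================

Each model supports prediction, linearization to straight-line coordinates,
ordinary-least-squares fitting on the linearized scale, and nonlinear
least squares on the original scale.  Fits are evaluated over configurable
stage windows (e.g. a burst stage of 1-8 h and a sustained stage out to
5 days for a two-stage hydrogel release profile).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .errors import (
    DomainError,
    ExhaustionWarning,
    FitError,
    InsufficientDataError,
    ParameterError,
)

MODELS = ("zero_order", "first_order", "higuchi", "korsmeyer_peppas", "hixson_crowell")

#: natural-log <-> log10 conversion used by the first-order model; the
#: customary "2.303" in the printed law log10 Q = k t / 2.303 is rounded ln 10
LOG10_E_INV = float(np.log(10.0))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ReleaseCurve:
    """Ordered time series of cumulative drug release.

    Parameters
    ----------
    times
        Sampling times in hours, strictly increasing, first >= 0.
    released
        Cumulative release at each time, either a fraction in [0, 1] or a
        percent in [0, 100] according to ``units``.
    units
        ``"fraction"`` or ``"percent"``.
    label
        Free-text identifier (formulation code etc.).
    """

    times: np.ndarray
    released: np.ndarray
    units: str = "percent"
    label: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.released = np.asarray(self.released, dtype=float)
        if self.units not in ("fraction", "percent"):
            raise DomainError(f"units must be 'fraction' or 'percent', got {self.units!r}")
        if self.times.ndim != 1 or self.times.shape != self.released.shape:
            raise DomainError("times and released must be 1-D arrays of equal length")
        if len(self.times) and self.times[0] < 0:
            raise DomainError("times must be non-negative")
        if np.any(np.diff(self.times) <= 0):
            raise DomainError("times must be strictly increasing")
        hi = 1.0 if self.units == "fraction" else 100.0
        if len(self.released) and (self.released.min() < -1e-12 or self.released.max() > hi * (1 + 1e-9)):
            raise DomainError(
                f"released values outside declared unit range [0, {hi:g}]"
            )

    def __len__(self):
        return len(self.times)

    @property
    def fractions(self) -> np.ndarray:
        """Release on the fraction scale regardless of declared units."""
        return self.released / 100.0 if self.units == "percent" else self.released

    @property
    def unit_scale(self) -> float:
        return 100.0 if self.units == "percent" else 1.0

    def validate(self) -> list[str]:
        """Flag (without fixing) violations of cumulative monotonicity."""
        out = []
        drops = np.nonzero(np.diff(self.released) < 0)[0]
        for i in drops:
            out.append(
                f"non-monotone cumulative release between t={self.times[i]:g} h "
                f"and t={self.times[i + 1]:g} h"
            )
        return out


@dataclass(frozen=True)
class StageWindow:
    """Closed time interval [t_start, t_end] (hours) over which a fit runs."""

    t_start: float
    t_end: float
    name: str = ""

    def __post_init__(self):
        if not self.t_start < self.t_end:
            raise DomainError(f"require t_start < t_end, got [{self.t_start}, {self.t_end}]")

    def mask(self, times: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the window (boundaries included)."""
        return (times >= self.t_start) & (times <= self.t_end)


#: the burst (1-8 h) and sustained (1-5 day) windows of the two-stage protocol
DEFAULT_WINDOWS = (
    StageWindow(1.0, 8.0, "first stage"),
    StageWindow(24.0, 120.0, "second stage"),
)


@dataclass
class KineticFit:
    """One classical model fitted on one stage window."""

    model_id: str
    params: dict
    r_squared: float
    window: StageWindow
    n_points: int
    method: str  # "linearized" | "nonlinear"
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model": self.model_id,
            "params": dict(self.params),
            "r_squared": self.r_squared,
            "window": {"t_start": self.window.t_start, "t_end": self.window.t_end,
                       "name": self.window.name},
            "n_points": self.n_points,
            "method": self.method,
            "warnings": list(self.warnings),
        }


@dataclass
class Linearized:
    """Straight-line coordinates (x', y') plus dropped-point bookkeeping."""

    x: np.ndarray
    y: np.ndarray
    n_dropped: int


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def _require(params: dict, keys: Sequence[str], model_id: str) -> None:
    missing = [k for k in keys if k not in params]
    if missing:
        raise ParameterError(f"{model_id} requires parameter(s) {missing}")


def predict(model_id: str, params: dict, t, w0: float | None = None):
    """Evaluate a classical model at times ``t`` (hours).

    Returns the model's natural quantity: cumulative release for
    ``zero_order``/``first_order``/``higuchi`` (in the caller's units),
    released *fraction* for ``korsmeyer_peppas``, and the *remaining* amount
    W_t for ``hixson_crowell`` (clamped at zero once the dose is exhausted,
    with an :class:`ExhaustionWarning`).
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("negative time")
    scalar = np.isscalar(t) or t_arr.ndim == 0

    if model_id == "zero_order":
        _require(params, ["k0"], model_id)
        out = params["k0"] * t_arr + params.get("intercept", 0.0)
    elif model_id == "first_order":
        # log10 Q = log10 Q0 + k t / 2.303  <=>  Q = Q0 exp(k t)
        _require(params, ["k"], model_id)
        out = params.get("q0", 1.0) * np.exp(params["k"] * t_arr)
    elif model_id == "higuchi":
        _require(params, ["kH"], model_id)
        out = params["kH"] * np.sqrt(t_arr) + params.get("intercept", 0.0)
    elif model_id == "korsmeyer_peppas":
        _require(params, ["k", "n"], model_id)
        out = params["k"] * np.power(t_arr, params["n"])
    elif model_id == "hixson_crowell":
        _require(params, ["k_release"], model_id)
        if w0 is None:
            w0 = params.get("w0")
        if w0 is None:
            raise ParameterError("hixson_crowell requires the initial amount w0")
        root = np.cbrt(w0) - params["k_release"] * t_arr
        if np.any(root < 0):
            warnings.warn("remaining amount clamped at 0 (dose exhausted)", ExhaustionWarning)
            root = np.maximum(root, 0.0)
        out = root ** 3
    else:
        raise ParameterError(f"unknown model {model_id!r}")
    return float(out) if scalar else out


# ---------------------------------------------------------------------------
# linearization
# ---------------------------------------------------------------------------

def linearize(model_id: str, curve: ReleaseCurve, window: StageWindow,
              w0: float | None = None, orientation: str = "table") -> Linearized:
    """Transform curve points in ``window`` to straight-line coordinates.

    zero_order -> (t, Q); first_order -> (t, log10 Q); higuchi -> (sqrt t, Q);
    korsmeyer_peppas -> (log10 t, log10 f); hixson_crowell -> (t, cube-root
    response).  Points whose log transform is undefined (zero release, or
    t = 0 for the power law) are dropped and counted.
    """
    m = window.mask(curve.times)
    t = curve.times[m]
    q = curve.released[m]
    n_dropped = 0

    if model_id == "zero_order":
        x, y = t, q
    elif model_id == "higuchi":
        x, y = np.sqrt(t), q
    elif model_id == "first_order":
        ok = q > 0
        n_dropped = int(np.sum(~ok))
        x, y = t[ok], np.log10(q[ok])
    elif model_id == "korsmeyer_peppas":
        f = q / curve.unit_scale
        ok = (f > 0) & (t > 0)
        n_dropped = int(np.sum(~ok))
        x, y = np.log10(t[ok]), np.log10(f[ok])
    elif model_id == "hixson_crowell":
        if w0 is None:
            w0 = curve.unit_scale  # full dose on the declared scale
        wt = w0 - q
        resp = np.cbrt(wt) - np.cbrt(w0)  # Table-1 orientation: negative slope
        if orientation == "release":
            resp = -resp  # printed law W0^(1/3) - Wt^(1/3): positive slope
        elif orientation != "table":
            raise ParameterError(f"unknown orientation {orientation!r}")
        x, y = t, resp
    else:
        raise ParameterError(f"unknown model {model_id!r}")

    if len(x) < 3:
        raise InsufficientDataError(
            f"{model_id}: {len(x)} usable points in window "
            f"[{window.t_start:g}, {window.t_end:g}] h (need >= 3)"
        )
    return Linearized(np.asarray(x, float), np.asarray(y, float), n_dropped)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_linear(model_id: str, curve: ReleaseCurve, window: StageWindow,
               w0: float | None = None, orientation: str = "table") -> KineticFit:
    """Ordinary least squares on the linearized coordinates.

    The slope maps back to the model's rate constant; for Korsmeyer-Peppas
    the slope is the release exponent n and the intercept is log10 k.
    R^2 is the coefficient of determination on the linearized scale.
    """
    lin = linearize(model_id, curve, window, w0=w0, orientation=orientation)
    if np.ptp(lin.x) == 0:
        raise FitError(f"{model_id}: degenerate design (all x' equal)")
    res = stats.linregress(lin.x, lin.y)
    slope, intercept = res.slope, res.intercept
    r2 = float(res.rvalue ** 2)
    warns = []
    if lin.n_dropped:
        warns.append(f"{lin.n_dropped} point(s) dropped by log transform")

    if model_id == "zero_order":
        params = {"k0": slope, "intercept": intercept}
    elif model_id == "first_order":
        # slope is on the log10 scale; the printed convention reports 2.303*slope
        k_origin = float(np.dot(lin.x, lin.y) / np.dot(lin.x, lin.x)) * LOG10_E_INV
        params = {"k": slope * LOG10_E_INV, "q0": 10.0 ** intercept,
                  "k_through_origin": k_origin}
    elif model_id == "higuchi":
        params = {"kH": slope, "intercept": intercept}
    elif model_id == "korsmeyer_peppas":
        params = {"k": 10.0 ** intercept, "n": slope}
    else:  # hixson_crowell
        if w0 is None:
            w0 = curve.unit_scale
        k_rel = -slope if orientation == "table" else slope
        params = {"k_hc": slope, "k_release": k_rel, "w0": w0, "intercept": intercept}

    return KineticFit(model_id, params, r2, window, len(lin.x), "linearized", warns)


def _model_on_data_scale(model_id: str, curve: ReleaseCurve, w0: float):
    """Return (model(t, *p), pnames, data y) for nonlinear fitting on the
    original (untransformed) scale."""
    m_scale = curve.unit_scale

    if model_id == "zero_order":
        return (lambda t, k0, c: k0 * t + c), ("k0", "intercept"), curve.released
    if model_id == "first_order":
        return (lambda t, k, q0: q0 * np.exp(k * t)), ("k", "q0"), curve.released
    if model_id == "higuchi":
        return (lambda t, kH, c: kH * np.sqrt(t) + c), ("kH", "intercept"), curve.released
    if model_id == "korsmeyer_peppas":
        return (lambda t, k, n: k * np.power(t, n)), ("k", "n"), curve.released / m_scale
    if model_id == "hixson_crowell":
        def f(t, k):
            return w0 - np.maximum(np.cbrt(w0) - k * t, 0.0) ** 3
        return f, ("k_release",), curve.released
    raise ParameterError(f"unknown model {model_id!r}")


def fit_nonlinear(model_id: str, curve: ReleaseCurve, window: StageWindow,
                  w0: float | None = None) -> KineticFit:
    """Least squares on the original scale, initialized from the linearized fit.

    On noiseless model-true data this agrees with :func:`fit_linear` to
    floating precision; on heteroscedastic data the two weightings differ and
    both are worth reporting.  R^2 here is computed on the original scale.
    """
    if w0 is None and model_id == "hixson_crowell":
        w0 = curve.unit_scale
    fun, pnames, _ = _model_on_data_scale(model_id, curve, w0)
    m = window.mask(curve.times)
    t = curve.times[m]
    y = (curve.released / curve.unit_scale if model_id == "korsmeyer_peppas"
         else curve.released)[m]
    if len(t) < len(pnames) + 1:
        raise InsufficientDataError(
            f"{model_id}: need >= {len(pnames) + 1} points, have {len(t)}")

    warns = []
    try:
        lin = fit_linear(model_id, curve, window, w0=w0)
        p0 = [lin.params[name] for name in pnames]
    except (FitError, InsufficientDataError):
        lin = None
        p0 = [0.1] * len(pnames)
        warns.append("linearized initialization unavailable; generic start used")

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(fun, t, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"{model_id}: nonlinear fit did not converge", fallback=lin) from exc

    yhat = fun(t, *popt)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    params = dict(zip(pnames, (float(p) for p in popt)))
    if model_id == "hixson_crowell":
        params["w0"] = w0
        params["k_hc"] = -params["k_release"]  # Table-1 sign convention
    return KineticFit(model_id, params, r2, window, len(t), "nonlinear", warns)


def summarize_fits(curve: ReleaseCurve, windows: Sequence[StageWindow] = DEFAULT_WINDOWS,
                   models: Sequence[str] = MODELS, w0: float | None = None,
                   method: str = "linearized") -> dict:
    """Fit every model over every window; errors are recorded per cell.

    Returns ``{window_name: {model_id: KineticFit | {"error": msg}}}`` — the
    rectangular layout of a release-kinetics results table (rows = stage,
    columns = model).  Use :func:`fit_grid_frame` for a flat DataFrame view.
    """
    for i, a in enumerate(windows):
        for b in windows[i + 1:]:
            if a.t_start <= b.t_end and b.t_start <= a.t_end:
                warnings.warn(f"windows {a.name or a} and {b.name or b} overlap")
    fit = fit_linear if method == "linearized" else fit_nonlinear
    grid: dict = {}
    for w in windows:
        row: dict = {}
        for mid in models:
            try:
                row[mid] = fit(mid, curve, w, w0=w0)
            except (InsufficientDataError, FitError, ParameterError) as exc:
                row[mid] = {"error": f"{type(exc).__name__}: {exc}"}
        grid[w.name or f"{w.t_start:g}-{w.t_end:g}h"] = row
    return grid


def fit_grid_frame(grid: dict):
    """Flatten a :func:`summarize_fits` grid to a tidy DataFrame
    (columns: window, model, r_squared, then one column per parameter)."""
    import pandas as pd

    rows = []
    for wname, row in grid.items():
        for mid, cell in row.items():
            if isinstance(cell, dict):
                rows.append({"window": wname, "model": mid, "error": cell["error"]})
            else:
                rec = {"window": wname, "model": mid, "r_squared": cell.r_squared,
                       "n_points": cell.n_points, "method": cell.method}
                rec.update(cell.params)
                rows.append(rec)
    return pd.DataFrame(rows)
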