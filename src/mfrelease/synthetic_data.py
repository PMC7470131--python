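"""Synthetic dissolution profiles with the structure the fits assume.

Emulates in-vitro release experiments on hydrogel formulations: a burst
stage over the first hours and a sustained stage over days, cumulative
release approaching a plateau well below 100%, multiplicative (relative)
measurement noise as produced by UV-Vis quantification, and the
aliquot-withdrawal-and-replacement sampling protocol (a fixed aliquot of the
dissolution medium is sampled at each timepoint and replaced with fresh
buffer, so measured concentrations must be corrected for previously removed
analyte).

Ground truth can be any classical kinetics model or a multifractal release
variant; every curve carries a sidecar record of the generating parameters
so recovery tests can close the loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import mf_release
from .errors import DomainError
from .kinetics import MODELS, ReleaseCurve, StageWindow, predict

__all__ = ["SyntheticConfig", "generate_release_curve", "default_schedule",
           "aliquot_correction", "concentrations_from_cumulative"]

_MF_MODELS = ("mf_exact", "mf_paper", "mf_early")


def default_schedule() -> np.ndarray:
    """Default sampling grid: hourly-scale points through the 8 h burst
    ({1, 2, 3, 4, 6, 8} h), then daily (24 h) steps out to 10 days (240 h)."""
    return np.concatenate([[1.0, 2.0, 3.0, 4.0, 6.0, 8.0],
                           np.arange(24.0, 241.0, 24.0)])


@dataclass
class SyntheticConfig:
    """Ground truth and measurement model for one synthetic curve.

    ``truth_model`` is a classical model id or one of ``mf_exact`` /
    ``mf_paper`` / ``mf_early`` (multifractal variants, parameterized by the
    reduced rate ``theta`` in 1/h).  ``truth_params`` holds one parameter
    dict per stage; stages are delimited by ``stage_bounds`` and joined
    continuously (each stage evaluated on stage-local time and shifted to
    the previous terminal value).  ``plateau`` is the terminal released
    fraction M_inf: for multifractal truths it multiplies f(theta t); for
    kinetics truths, when not None, the curve is rescaled so its final value
    equals the plateau.  Noise is multiplicative Gaussian of relative sd
    ``noise_sd`` (or additive when ``noise_model="additive_gaussian"``).
    """

    truth_model: str = "mf_exact"
    truth_params: Sequence[dict] = field(default_factory=lambda: [{"theta": 0.04}])
    stage_bounds: Sequence[StageWindow] | None = None
    plateau: float | None = 0.70
    noise_model: str = "multiplicative_gaussian"
    noise_sd: float = 0.0
    schedule: np.ndarray = field(default_factory=default_schedule)
    seed: int = 0
    units: str = "fraction"
    label: str = "synthetic"
    aliquot: tuple[float, float] | None = None  # (vessel volume, aliquot volume)

    def __post_init__(self):
        self.schedule = np.asarray(self.schedule, dtype=float)
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be >= 0")
        if self.plateau is not None and not 0 < self.plateau <= 1:
            raise DomainError("plateau must lie in (0, 1]")
        if np.any(np.diff(self.schedule) <= 0):
            raise DomainError("schedule must be strictly increasing")
        if self.noise_model not in ("none", "multiplicative_gaussian", "additive_gaussian"):
            raise DomainError(f"unknown noise model {self.noise_model!r}")
        if self.truth_model not in MODELS + _MF_MODELS:
            raise DomainError(f"unknown truth model {self.truth_model!r}")
        if self.aliquot is not None and not self.aliquot[1] < self.aliquot[0]:
            raise DomainError("aliquot volume must be smaller than vessel volume")
        n_stages = 1 if self.stage_bounds is None else len(self.stage_bounds)
        if len(self.truth_params) != n_stages:
            raise DomainError("need one parameter set per stage")


def _truth_value(model: str, params: dict, t: np.ndarray,
                 shift: bool = False) -> np.ndarray:
    """Stage model on stage-local time; ``shift`` zeroes it at t = 0
    (used only when joining stages continuously)."""
    if model == "mf_exact":
        return mf_release.release_fraction_exact(params["theta"] * t)
    if model == "mf_paper":
        return mf_release.release_fraction_paper(params["theta"] * t)
    if model == "mf_early":
        return mf_release.release_fraction_early(params["theta"] * t)
    if model == "hixson_crowell":
        w0 = params.get("w0", 1.0)
        wt = predict(model, params, t, w0=w0)
        return w0 - wt  # cumulative release implied by the cube-root law
    v = np.asarray(predict(model, params, t))
    return v - predict(model, params, 0.0) if shift else v


def generate_release_curve(config: SyntheticConfig):
    """Evaluate the truth model on the schedule, apply the measurement model.

    Returns ``(curve, ground_truth)`` where ``ground_truth`` records the
    generating model, per-stage parameters, plateau, noise and seed.
    Deterministic for a fixed seed.
    """
    cfg = config
    t = cfg.schedule
    if cfg.stage_bounds is None:
        clean = _truth_value(cfg.truth_model, cfg.truth_params[0], t)
        if cfg.truth_model in _MF_MODELS and cfg.plateau is not None:
            clean = cfg.plateau * clean
    else:
        # stage i stays active until the next stage begins (last stage to the
        # end of the schedule); each stage runs on its own clock and is
        # shifted to the previous terminal value, so the curve is continuous
        clean = np.zeros_like(t)
        starts = [w.t_start for w in cfg.stage_bounds] + [np.inf]
        offset = 0.0
        for i, (w, p) in enumerate(zip(cfg.stage_bounds, cfg.truth_params)):
            seg = (t >= starts[i]) & (t < starts[i + 1])
            local = np.maximum(t - w.t_start, 0.0)
            vals = np.asarray(_truth_value(cfg.truth_model, p, local, shift=True))
            clean[seg] = offset + vals[seg]
            if np.isfinite(starts[i + 1]):
                offset += float(_truth_value(
                    cfg.truth_model, p,
                    np.array([starts[i + 1] - w.t_start]), shift=True)[0])
        if cfg.truth_model in _MF_MODELS and cfg.plateau is not None:
            clean = cfg.plateau * clean
    if (cfg.truth_model not in _MF_MODELS and cfg.plateau is not None
            and clean[-1] > 0):
        clean = clean * (cfg.plateau * (100.0 if cfg.units == "percent" else 1.0)
                         / clean[-1])

    rng = np.random.default_rng(cfg.seed)
    values = clean.copy()
    if cfg.noise_model == "multiplicative_gaussian" and cfg.noise_sd > 0:
        values = values * (1.0 + cfg.noise_sd * rng.standard_normal(len(values)))
    elif cfg.noise_model == "additive_gaussian" and cfg.noise_sd > 0:
        values = values + cfg.noise_sd * rng.standard_normal(len(values))
    values = np.maximum(values, 0.0)

    if cfg.aliquot is not None:
        # simulate what the spectrophotometer sees, then correct it back:
        # the round trip is exact, but the sidecar keeps the concentrations
        v_total, v_aliquot = cfg.aliquot
        conc = concentrations_from_cumulative(values, v_total, v_aliquot)
        values = aliquot_correction(conc, v_total, v_aliquot)

    curve = ReleaseCurve(times=t, released=values, units=cfg.units, label=cfg.label)
    truth = {
        "truth_model": cfg.truth_model,
        "truth_params": [dict(p) for p in cfg.truth_params],
        "plateau": cfg.plateau,
        "noise_model": cfg.noise_model,
        "noise_sd": cfg.noise_sd,
        "seed": cfg.seed,
        "clean": clean,
    }
    return curve, truth


# ---------------------------------------------------------------------------
# aliquot accounting
# ---------------------------------------------------------------------------

def aliquot_correction(concentrations, v_total: float, v_aliquot: float) -> np.ndarray:
    """Cumulative released amounts from measured aliquot concentrations.

    At step j the vessel holds c_j * v_total of analyte, and the prior
    aliquots removed v_aliquot * sum_{i<j} c_i, so the cumulative amount is

        M_j = c_j * v_total + v_aliquot * sum_{i<j} c_i.
    """
    c = np.asarray(concentrations, dtype=float)
    if np.any(c < 0):
        raise DomainError("concentrations must be non-negative")
    if not 0 <= v_aliquot < v_total:
        raise DomainError("require 0 <= v_aliquot < v_total")
    prior = np.concatenate([[0.0], np.cumsum(c)[:-1]])
    return c * v_total + v_aliquot * prior


def concentrations_from_cumulative(amounts, v_total: float, v_aliquot: float) -> np.ndarray:
    """Inverse of :func:`aliquot_correction` (simulates measured concentrations)."""
    m = np.asarray(amounts, dtype=float)
    if not 0 <= v_aliquot < v_total:
        raise DomainError("require 0 <= v_aliquot < v_total")
    c = np.empty_like(m)
    removed = 0.0
    for j in range(len(m)):
        c[j] = (m[j] - v_aliquot * removed) / v_total
        removed += c[j]
    if np.any(c < -1e-12):
        raise DomainError("cumulative amounts imply negative concentrations")
    return c
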