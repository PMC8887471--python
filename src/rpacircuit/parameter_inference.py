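"""Fitting of promoter response curves and of the full circuit model.

Two fitting problems arise when characterising the circuit:

* **Hill response curves** — steady-state dose-response data of a single
  regulated promoter are fit with the activating Hill form
  ``alpha_max * (x^n/(K^n + x^n) + beta)``.  Because fluorescence spans
  decades, the objective is least squares on log10 responses.

* **Circuit time courses** — stepped and control time courses are fit with
  the full ODE model by minimising summed squared log10 residuals over all
  series with a multi-start downhill simplex (Nelder-Mead), holding every
  parameter outside the ``free`` set at its initial value.

A fitted circuit predicts promoter-substitution experiments by replacing
only the buffer-node promoter strength ``alpha2`` and re-simulating, with
no refitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import lmfit
from scipy.optimize import least_squares, minimize

from .circuit_model import (CircuitParameters, StepExperiment, Trajectory,
                            SteadyStateError, SimulationError, simulate_step)

__all__ = [
    "DoseResponseData",
    "FitResult",
    "ObservedStepResponse",
    "UnidentifiableFitError",
    "fit_hill",
    "fit_circuit",
    "predict_substitution",
]


class UnidentifiableFitError(ValueError):
    """Raised when the data cannot constrain the requested parameters."""


@dataclass
class DoseResponseData:
    """Mean +/- SD dose-response table (inducer or activator vs output)."""

    doses: np.ndarray
    responses: np.ndarray
    sds: np.ndarray
    n_reps: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if not (len(self.doses) == len(self.responses) == len(self.sds)):
            raise ValueError("doses, responses and sds must have equal length")
        if np.any(self.doses < 0):
            raise ValueError("doses must be non-negative")
        if not np.all(np.diff(self.doses) > 0):
            raise ValueError("doses must be strictly increasing")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass
class FitResult:
    """Outcome of a multi-start fit."""

    parameters: Dict[str, float]
    loss: float
    n_restarts_used: int
    converged: bool
    covariance_proxy: Dict[str, float]  # per-parameter spread across restarts
    history: List[float] = field(default_factory=list)  # best loss per accepted step


@dataclass
class ObservedStepResponse:
    """One step experiment with observed stepped and control output series."""

    experiment: StepExperiment
    stepped: np.ndarray
    control: np.ndarray
    stepped_sd: Optional[np.ndarray] = None
    control_sd: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.stepped = np.asarray(self.stepped, dtype=float)
        self.control = np.asarray(self.control, dtype=float)
        m = len(self.experiment.t_grid)
        if len(self.stepped) != m or len(self.control) != m:
            raise ValueError("observed series must align with the experiment t_grid")


# ---------------------------------------------------------------------------
# Hill curve fitting


def _hill_model(doses, alpha_max, K, n, beta):
    # direct form rather than the circuit kernel: dose-response fits allow
    # apparent cooperativities below 1
    r = (np.asarray(doses, dtype=float) / K) ** n
    return alpha_max * (r / (1.0 + r) + beta)


def fit_hill(data: DoseResponseData, seed: int = 0,
             n_restarts: int = 8) -> FitResult:
    """Fit ``alpha_max * (x^n/(K^n + x^n) + beta)`` to a dose-response table.

    Least squares of log10(model) against log10(response), multi-start
    bounded Nelder-Mead followed by a trust-region polish.  Bounds:
    ``n`` in [0.5, 4], ``K`` within the dose range x[0.1, 10].  Raises
    :class:`UnidentifiableFitError` for flat data (< 2-fold response range).
    """
    pos = data.doses > 0
    if np.count_nonzero(pos) < 5:
        raise ValueError("need >= 5 distinct positive doses")
    if np.any(data.responses <= 0):
        raise ValueError("responses must be positive for a log-scale fit")
    if data.responses.max() / data.responses.min() < 2.0:
        raise UnidentifiableFitError(
            "response range below 2-fold: Hill coefficient unidentifiable")

    x = data.doses[pos]
    y = np.log10(data.responses[pos])
    k_lo, k_hi = 0.1 * x.min(), 10.0 * x.max()
    a_hi = 100.0 * data.responses.max()

    def residuals(params):
        m = _hill_model(x, params["alpha_max"], params["K"], params["n"],
                        params["beta"])
        return np.log10(np.maximum(m, 1e-300)) - y

    rng = np.random.default_rng(seed)
    best = None
    losses = []
    samples = []
    for i in range(n_restarts):
        params = lmfit.Parameters()

        def jitter() -> float:
            return float(np.exp(rng.normal(0.0, 0.7))) if i else 1.0

        params.add("alpha_max", value=min(data.responses.max() * jitter(), a_hi),
                   min=1e-12, max=a_hi)
        params.add("K", value=float(np.clip(np.sqrt(x.min() * x.max()) * jitter(),
                                            k_lo, k_hi)), min=k_lo, max=k_hi)
        params.add("n", value=float(np.clip(1.0 + rng.uniform(0, 1.5) * (i > 0),
                                            0.5, 4.0)), min=0.5, max=4.0)
        params.add("beta", value=0.01 * jitter(), min=1e-8, max=1.0)
        try:
            res = lmfit.minimize(residuals, params, method="nelder",
                                 options={"maxfev": 4000, "xatol": 1e-10,
                                          "fatol": 1e-12})
            res = lmfit.minimize(residuals, res.params, method="least_squares")
        except Exception:
            continue
        loss = float(np.sum(np.asarray(res.residual) ** 2))
        vals = {k: float(res.params[k].value) for k in res.params}
        losses.append(loss)
        samples.append(vals)
        if best is None or loss < best[0]:
            best = (loss, vals)
    if best is None:
        raise RuntimeError("all Hill-fit restarts failed")
    spread = _restart_spread(samples, losses, best[0])
    return FitResult(parameters=best[1], loss=best[0],
                     n_restarts_used=len(losses), converged=True,
                     covariance_proxy=spread, history=sorted(losses, reverse=True))


def _restart_spread(samples: List[dict], losses: List[float],
                    best_loss: float) -> Dict[str, float]:
    """Relative spread of near-optimal restarts (identifiability proxy)."""
    good = [s for s, l in zip(samples, losses)
            if l <= best_loss * 1.5 + 1e-12]
    if len(good) < 2:
        return {k: 0.0 for k in samples[0]}
    out = {}
    for k in good[0]:
        v = np.array([g[k] for g in good])
        out[k] = float(np.std(v) / (abs(np.mean(v)) + 1e-300))
    return out


# ---------------------------------------------------------------------------
# Circuit fitting


def _simulate_outputs(p: CircuitParameters, exp: StepExperiment,
                      rtol: float, atol: float):
    stepped, control = simulate_step(exp, p, rtol=rtol, atol=atol)
    return stepped.output, control.output


def fit_circuit(datasets: Sequence[ObservedStepResponse],
                p_init: CircuitParameters,
                free: Iterable[str],
                seed: int = 0,
                n_restarts: int = 20,
                rtol: float = 1e-7,
                atol: float = 1e-9,
                maxfev: int = 800) -> FitResult:
    """Fit free circuit parameters to stepped + control time courses.

    Minimises the summed squared log10 residuals over all series by
    multi-start Nelder-Mead in log-parameter space (free parameters are
    positive rates/affinities).  Residuals are weighted by 1/SD when per-time
    SDs are provided (i.e. 1/SD^2 weights on the squared loss).  Restart
    initial points jitter the ``p_init`` values; restart 0 starts exactly at
    ``p_init``.
    """
    free = list(free)
    if not free:
        raise ValueError("free parameter set must be non-empty")
    valid = set(CircuitParameters.__dataclass_fields__) - {
        "self_activation_form", "variant", "c_pf"}
    unknown = [f for f in free if f not in valid]
    if unknown:
        raise ValueError(f"unknown free parameter name(s): {', '.join(unknown)}")
    if not datasets:
        raise ValueError("need at least one observed step dataset")
    for d in datasets:
        if np.any(d.stepped <= 0) or np.any(d.control <= 0):
            raise ValueError("observed outputs must be positive for log-scale fitting")

    x0 = np.log([getattr(p_init, f) for f in free])

    n_eval = 0

    def objective(logx) -> float:
        nonlocal n_eval
        n_eval += 1
        try:
            p = p_init.with_updates(**dict(zip(free, np.exp(logx))))
        except ValueError:
            return 1e12
        total = 0.0
        for d in datasets:
            try:
                sim_s, sim_c = _simulate_outputs(p, d.experiment, rtol, atol)
            except (SteadyStateError, SimulationError):
                return 1e12
            if np.any(sim_s <= 0) or np.any(sim_c <= 0):
                return 1e12
            for sim, obs, sd in ((sim_s, d.stepped, d.stepped_sd),
                                 (sim_c, d.control, d.control_sd)):
                r = np.log10(sim) - np.log10(obs)
                if sd is not None:
                    w = (np.asarray(obs) / (np.asarray(sd) + 1e-300)) ** 2
                    w = w / np.mean(w)
                    total += float(np.sum(w * r * r))
                else:
                    total += float(np.sum(r * r))
        return total

    rng = np.random.default_rng(seed)
    best = None
    samples = []
    losses = []
    histories = []
    n_used = 0
    for i in range(n_restarts):
        start = x0 if i == 0 else x0 + rng.normal(0.0, 0.7, size=len(free))
        hist: List[float] = []

        cache = {}

        def recording_objective(xx):
            v = objective(xx)
            cache[tuple(np.round(xx, 12))] = v
            return v

        def on_step(xk):
            v = cache.get(tuple(np.round(xk, 12)))
            if v is None:
                v = objective(xk)
            if not hist or v <= hist[-1]:
                hist.append(v)

        res = minimize(recording_objective, start, method="Nelder-Mead",
                       callback=on_step,
                       options={"maxfev": maxfev, "xatol": 1e-9, "fatol": 1e-12})
        n_used += 1
        if not np.isfinite(res.fun) or res.fun >= 1e12:
            continue
        vals = dict(zip(free, np.exp(res.x)))
        losses.append(float(res.fun))
        samples.append(vals)
        histories.append(hist)
        if best is None or res.fun < best[0]:
            best = (float(res.fun), vals, hist)
    if best is None:
        raise RuntimeError(
            f"all {n_restarts} circuit-fit restarts failed "
            f"({n_eval} objective evaluations)")
    spread = _restart_spread(samples, losses, best[0])
    return FitResult(parameters=best[1], loss=best[0], n_restarts_used=n_used,
                     converged=True, covariance_proxy=spread, history=best[2])


def predict_substitution(p_fitted: CircuitParameters, alpha2_new: float,
                         experiments: Sequence[StepExperiment]
                         ) -> List[Tuple[Trajectory, Trajectory]]:
    """Predict step responses after substituting the B-node promoter strength.

    Replaces ``alpha2`` only and re-simulates every experiment with the
    otherwise unchanged fitted parameter set (no refitting).  Returns one
    (stepped, control) trajectory pair per experiment.
    """
    if not (np.isfinite(alpha2_new) and alpha2_new > 0):
        raise ValueError("alpha2_new must be > 0")
    p = p_fitted.with_updates(alpha2=alpha2_new)
    return [simulate_step(exp, p) for exp in experiments]
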