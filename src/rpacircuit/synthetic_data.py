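"""Cytometry-like synthetic dose-response and time-course datasets.

Mean-fluorescence readouts from flow cytometry have error bars roughly
proportional to the mean, so replicates are modelled with multiplicative
log-normal noise of a chosen coefficient of variation (CV): each replicate
is the noiseless model signal times ``exp(sigma*z - sigma^2/2)`` with
``sigma = sqrt(log(1 + cv^2))``, which has unit mean and exact CV ``cv``.
Three replicates at CV = 0.1 is the default, emulating triplicate plate
measurements.  Noise is strictly multiplicative: positive signals stay
positive at any CV.

Growth-dilution effects of the serial-dilution harvesting protocol are not
modelled mechanistically; dilution is folded into the removal rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circuit_model import (CircuitParameters, StepExperiment,
                            SteadyStateError, simulate_step, steady_state)
from .parameter_inference import DoseResponseData

__all__ = [
    "NoiseModel",
    "generate_dose_response",
    "generate_timecourse",
    "generate_promoter_panel",
]


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative log-normal replicate noise."""

    cv: float = 0.1
    n_reps: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    @property
    def sigma(self) -> float:
        return float(np.sqrt(np.log1p(self.cv ** 2)))

    def factors(self, rng: np.random.Generator, shape) -> np.ndarray:
        """Unit-mean multiplicative noise factors."""
        if self.cv == 0:
            return np.ones(shape)
        s = self.sigma
        return np.exp(s * rng.standard_normal(shape) - 0.5 * s * s)


def generate_dose_response(p: CircuitParameters, doses, noise: NoiseModel
                           ) -> DoseResponseData:
    """Steady-state output vs inducer dose with replicate noise.

    For each dose the circuit is equilibrated and the output (node A) read
    out per replicate with multiplicative noise; the table holds per-dose
    mean and SD.  Deterministic given ``noise.seed``.
    """
    doses = np.asarray(doses, dtype=float)
    rng = np.random.default_rng(noise.seed)
    means, sds = [], []
    for d in doses:
        try:
            ss = steady_state(d, p)
        except SteadyStateError as exc:
            raise SteadyStateError(f"steady state failed at dose {d} uM: {exc}")
        reps = ss.A * noise.factors(rng, noise.n_reps)
        means.append(float(np.mean(reps)))
        sds.append(float(np.std(reps, ddof=1)) if noise.n_reps > 1 else 0.0)
    return DoseResponseData(doses=doses, responses=np.array(means),
                            sds=np.array(sds), n_reps=noise.n_reps,
                            meta={"seed": noise.seed, "cv": noise.cv})


def generate_timecourse(exp: StepExperiment, p: CircuitParameters,
                        noise: NoiseModel):
    """Noisy stepped and control time-course tables (long format).

    Both series share the same pre-equilibrated baseline trajectory from the
    simulator.  Each row is one replicate observation: columns ``time_h``,
    ``replicate``, ``output``, ``series``, ``input_uM``.  Deterministic
    given ``noise.seed``.
    """
    stepped, control = simulate_step(exp, p)
    rng = np.random.default_rng(noise.seed)
    tables = []
    for traj in (stepped, control):
        f = noise.factors(rng, (len(traj.times), noise.n_reps))
        obs = traj.output[:, None] * f
        df = pd.DataFrame({
            "time_h": np.repeat(traj.times, noise.n_reps),
            "replicate": np.tile(np.arange(1, noise.n_reps + 1), len(traj.times)),
            "output": obs.ravel(),
            "series": traj.series,
            "input_uM": traj.input_level,
        })
        tables.append(df)
    return tables[0], tables[1]


def summarize_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a long-format replicate table to per-time mean and SD."""
    g = table.groupby("time_h", sort=True)["output"]
    out = pd.DataFrame({"time_h": sorted(table["time_h"].unique()),
                        "output": g.mean().to_numpy(),
                        "sd": g.std(ddof=1).fillna(0.0).to_numpy()})
    out["series"] = table["series"].iloc[0]
    out["input_uM"] = table["input_uM"].iloc[0]
    return out


def generate_promoter_panel(n_true_range=(1.0, 1.3),
                            activity_range_fold: float = 150.0,
                            n_promoters: int = 6,
                            noise: NoiseModel = NoiseModel(),
                            doses=None, K_true: float = 5.0,
                            beta_true: float = 0.01):
    """Panel of activation curves for promoter mutants of one activator.

    Maximal activities are log-spaced to span exactly
    ``activity_range_fold`` (a single promoter gets the geometric mid
    activity); true Hill coefficients are drawn uniformly in
    ``n_true_range``.  Each curve is a :class:`DoseResponseData` whose
    ``meta`` records the generating truth, making the panel a recovery
    fixture for :func:`~rpacircuit.parameter_inference.fit_hill`.
    """
    if n_promoters < 1:
        raise ValueError("n_promoters must be >= 1")
    if activity_range_fold < 1:
        raise ValueError("activity_range_fold must be >= 1")
    if doses is None:
        doses = np.geomspace(0.05, 100.0, 9)
    doses = np.asarray(doses, dtype=float)
    rng = np.random.default_rng(noise.seed)
    base = 100.0
    if n_promoters == 1:
        alphas = np.array([base * np.sqrt(activity_range_fold)])
    else:
        alphas = base * np.geomspace(1.0, activity_range_fold, n_promoters)
    panel = []
    for a in alphas:
        n_true = float(rng.uniform(*n_true_range))
        signal = a * ((doses / K_true) ** n_true
                      / (1.0 + (doses / K_true) ** n_true) + beta_true)
        reps = signal[:, None] * noise.factors(rng, (len(doses), noise.n_reps))
        means = reps.mean(axis=1)
        sds = reps.std(axis=1, ddof=1) if noise.n_reps > 1 else np.zeros(len(doses))
        panel.append(DoseResponseData(
            doses=doses, responses=means, sds=sds, n_reps=noise.n_reps,
            meta={"alpha_max": float(a), "K": K_true, "n": n_true,
                  "beta": beta_true, "seed": noise.seed, "cv": noise.cv}))
    return panel
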