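"""Adaptation statistics for step-response trajectories.

The adaptation error of a step response is

    AErr = |Output1 - Output2| / Output1

where ``Output1`` is the settled output of the stepped series (mean of its
final few samples) and ``Output2`` the steady output of an unswitched
control held at the pre-step input (mean over all its samples).  AErr = 0 is
perfect adaptation; values can exceed 1 when the output settles far from
the control level.  A circuit counts as *adapting* when it both responds
(transient peak sufficiently above baseline) and returns (small AErr).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Tuple

import numpy as np

from .circuit_model import Trajectory

__all__ = [
    "AdaptationResult",
    "adaptation_error",
    "steady_outputs",
    "pulse_metrics",
    "classify_adaptation",
    "evaluate_step_response",
    "DEFAULT_SENS_MIN",
    "DEFAULT_AERR_MAX",
]

#: Default classification thresholds: minimum relative pulse height
#: (peak_fold - 1) for a circuit to count as responsive, and the maximum
#: AErr for an adapted response.
DEFAULT_SENS_MIN = 0.5
DEFAULT_AERR_MAX = 0.1


@dataclass(frozen=True)
class AdaptationResult:
    """Adaptation summary of one stepped/control trajectory pair."""

    output1: float  # settled output of the stepped series (a.u.)
    output2: float  # steady output of the constant-input control (a.u.)
    aerr: float
    peak_value: float  # maximal transient output (a.u.)
    peak_fold: float  # peak_value / output2
    peak_time: float  # hours after the switch
    adapts: bool
    responsive: bool = True
    failed: bool = False
    failure_reason: Optional[str] = None

    def to_dict(self) -> dict:
        return asdict(self)


def adaptation_error(output1: float, output2: float) -> float:
    """``|output1 - output2| / output1``; requires output1 > 0."""
    if not np.isfinite(output1) or output1 <= 0:
        raise ValueError(f"adaptation error undefined for output1={output1}")
    if not np.isfinite(output2) or output2 < 0:
        raise ValueError(f"output2 must be finite and >= 0, got {output2}")
    return abs(output1 - output2) / output1


def steady_outputs(stepped: Trajectory, control: Trajectory,
                   tail_n: int = 3) -> Tuple[float, float]:
    """(Output1, Output2): stepped tail mean and control overall mean.

    Output1 averages the final ``tail_n`` samples of the stepped series
    (the post-step plateau); Output2 averages *all* samples of the control
    series, mirroring how the unswitched reference level is measured.
    """
    if tail_n < 1:
        raise ValueError("tail_n must be >= 1")
    if len(stepped.output) < tail_n:
        raise ValueError(
            f"stepped series has {len(stepped.output)} < tail_n={tail_n} samples")
    if len(control.output) < 1:
        raise ValueError("control series is empty")
    out1 = float(np.mean(stepped.output[-tail_n:]))
    out2 = float(np.mean(control.output))
    return out1, out2


def pulse_metrics(stepped: Trajectory, output2: float,
                  refine: int = 20) -> Tuple[float, float, float]:
    """(peak_value, peak_fold, peak_time) of the transient response.

    When the trajectory carries a dense interpolant, the peak is located on
    a grid refined ``refine``-fold rather than only at the sample times.
    """
    if len(stepped.output) == 0:
        raise ValueError("empty trajectory")
    if not np.isfinite(output2) or output2 <= 0:
        raise ValueError(f"baseline output2 must be > 0, got {output2}")
    t = stepped.times
    y = stepped.output
    if stepped.dense is not None and len(t) > 1:
        tf = np.linspace(t[0], t[-1], refine * (len(t) - 1) + 1)
        yf = stepped.dense(tf)[0]
        # keep sample points too, so the peak never falls below the grid max
        t = np.concatenate([t, tf])
        y = np.concatenate([y, yf])
        order = np.argsort(t)
        t, y = t[order], y[order]
    i = int(np.argmax(y))
    peak_value = float(y[i])
    return peak_value, peak_value / output2, float(t[i])


def classify_adaptation(result: AdaptationResult,
                        sens_min: float = DEFAULT_SENS_MIN,
                        aerr_max: float = DEFAULT_AERR_MAX) -> bool:
    """Adapting = responded (peak_fold - 1 >= sens_min) and returned
    (aerr <= aerr_max)."""
    return bool(result.peak_fold - 1.0 >= sens_min and result.aerr <= aerr_max)


def evaluate_step_response(stepped: Trajectory, control: Trajectory,
                           tail_n: int = 3,
                           sens_min: float = DEFAULT_SENS_MIN,
                           aerr_max: float = DEFAULT_AERR_MAX) -> AdaptationResult:
    """Full adaptation summary of one simulated or measured step response."""
    out1, out2 = steady_outputs(stepped, control, tail_n=tail_n)
    peak_value, peak_fold, peak_time = pulse_metrics(stepped, out2)
    aerr = adaptation_error(out1, out2)
    responsive = peak_fold - 1.0 >= sens_min
    partial = AdaptationResult(out1, out2, aerr, peak_value, peak_fold,
                               peak_time, adapts=False, responsive=responsive)
    return AdaptationResult(out1, out2, aerr, peak_value, peak_fold, peak_time,
                            adapts=classify_adaptation(partial, sens_min, aerr_max),
                            responsive=responsive)
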