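"""In-silico robustness screen over sampled parameter cassettes.

The screen draws complete circuit parameter sets ("cassettes") log-uniformly
from wide ranges, simulates a reference input step for each, and classifies
the response (responsive/adapting) with the adaptation-error metric.  Paired
runs of the same cassettes under different structural variants (full
topology vs null positive feedback, etc.) quantify how indispensable the
buffer-node positive feedback is for perfect adaptation.

The module also provides the single-edge perturbation sweep: scaling one
regulatory edge's strength by fold factors and measuring the adaptation
error, mirroring promoter-mutant and guide-RNA substitutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .adaptation_metrics import (AdaptationResult, DEFAULT_AERR_MAX,
                                 DEFAULT_SENS_MIN, evaluate_step_response)
from .circuit_model import (CircuitParameters, CircuitState, StepExperiment,
                            SimulationError, SteadyStateError, simulate_step,
                            steady_state)

__all__ = [
    "ParameterRanges",
    "ScanReport",
    "Thresholds",
    "default_ranges",
    "sample_parameters",
    "evaluate_cassette",
    "scan_cassettes",
    "scan_topology",
    "edge_perturbation_sweep",
    "matched_c_pf",
    "apply_variant",
    "weak_linear_regime",
    "DEFAULT_SCAN_STEP",
]

EDGES = ("self_activation", "B_to_A", "A_to_B")

#: Parameters drawn log-uniformly by default (rates and affinities).
LOG_UNIFORM = ("alpha1", "alpha2", "K_TFtot", "K_IR", "K_BA", "K_AB", "K_BB")
#: Hill coefficients are drawn uniformly from the integer grid {1..4}.
HILL_COEFFS = ("n_RA", "n_BA", "n_AB", "n_BB")

#: Reference screen step: 2 -> 200 uM over 24 h at 0.1 h resolution.
DEFAULT_SCAN_STEP = StepExperiment(2.0, 200.0, np.arange(0.0, 24.0 + 1e-9, 0.1))


@dataclass(frozen=True)
class Thresholds:
    """Classification thresholds, always serialized into scan reports."""

    sens_min: float = DEFAULT_SENS_MIN
    aerr_max: float = DEFAULT_AERR_MAX
    tail_n: int = 3


@dataclass
class ParameterRanges:
    """Sampling specification for the cassette screen.

    ``ranges`` maps parameter names to (low, high) bounds; rate/affinity
    parameters are sampled log-uniformly, Hill coefficients uniformly on the
    integer grid spanned by their bounds.  ``fixed`` pins parameters to
    exact values.  Removal rates default to 1 (time-scale normalisation) and
    leaks to small fixed values: 0.01 for the input-drive, activation and
    repression edges, 1e-4 for the buffer self-activation whose physical
    promoter is near-silent without its activator.
    """

    ranges: Dict[str, Tuple[float, float]]
    fixed: Dict[str, float] = field(default_factory=dict)
    n_samples: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for k, (lo, hi) in self.ranges.items():
            if not (lo < hi):
                raise ValueError(f"range for {k} must satisfy low < high, got ({lo}, {hi})")
            if k in LOG_UNIFORM and lo <= 0:
                raise ValueError(f"log-uniform range for {k} must be positive")


def default_ranges(n_samples: int = 200, seed: int = 0,
                   **fixed_overrides) -> ParameterRanges:
    """Wide default screen ranges: alpha in [0.1, 1000], K in [0.01, 100].

    The screen varies the circuit-internal parameters; the input-drive
    module (inducer/repressor constants K_TFtot, K_IR, n_RA) is held at its
    characterised design values so that every cassette receives the same
    external stimulus — the screen asks whether the *network* adapts, not
    whether the inducer module responds.
    """
    ranges = {"alpha1": (0.1, 1000.0), "alpha2": (0.1, 1000.0),
              "K_BA": (0.01, 100.0), "K_AB": (0.01, 100.0),
              "K_BB": (0.01, 100.0),
              "n_BA": (1, 4), "n_AB": (1, 4), "n_BB": (1, 4)}
    fixed = {"gammaA": 1.0, "gammaB": 1.0,
             "K_TFtot": 3.0, "K_IR": 1.0, "n_RA": 1.0,
             "beta_RA": 0.01, "beta_BA": 0.01, "beta_AB": 0.01,
             "beta_BB": 1e-4}
    for k, v in fixed_overrides.items():
        fixed[k] = v
        ranges.pop(k, None)
    return ParameterRanges(ranges=ranges, fixed=fixed,
                           n_samples=n_samples, seed=seed)


def sample_parameters(ranges: ParameterRanges) -> List[CircuitParameters]:
    """Draw ``n_samples`` cassettes; deterministic given ``ranges.seed``."""
    rng = np.random.default_rng(ranges.seed)
    out = []
    names = sorted(ranges.ranges)  # fixed draw order for determinism
    for _ in range(ranges.n_samples):
        d = dict(ranges.fixed)
        for k in names:
            lo, hi = ranges.ranges[k]
            if k in HILL_COEFFS:
                d[k] = float(rng.integers(int(lo), int(hi) + 1))
            else:
                d[k] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        d.setdefault("self_activation_form", "hill")
        d.setdefault("variant", "full")
        out.append(CircuitParameters.from_dict(d))
    return out


def matched_c_pf(p_full: CircuitParameters, input_initial: float,
                 multiple: float = 1.0) -> float:
    """Constitutive level as a multiple of the operating self-activation.

    Computes the full circuit's steady state at the pre-step input and
    returns ``multiple`` times its self-activation factor there, so that
    null-PF circuits of "different strengths" are comparable across
    parameter sets.
    """
    base = p_full.with_updates(variant="full", c_pf=None)
    ss = steady_state(input_initial, base)
    return multiple * float(base.self_activation(ss.B))


def apply_variant(p: CircuitParameters, variant: str,
                  input_initial: float = 2.0,
                  c_pf_multiple: float = 1.0) -> CircuitParameters:
    """Re-express a cassette under a structural variant.

    ``null_pf`` gets its constitutive level matched to the full circuit's
    operating point via :func:`matched_c_pf`; ``nonlinear_pf`` switches to
    cooperative self-activation with the characterised coefficient 2.3.
    """
    if variant == "full":
        return p.with_updates(variant="full", c_pf=None)
    if variant == "null_pf":
        c = matched_c_pf(p, input_initial, c_pf_multiple)
        return p.with_updates(variant="null_pf", c_pf=c)
    if variant == "nonlinear_pf":
        return p.with_updates(variant="nonlinear_pf", n_BB=2.3,
                              self_activation_form="hill", c_pf=None)
    if variant == "no_repression":
        return p.with_updates(variant="no_repression", c_pf=None)
    raise ValueError(f"unknown variant {variant!r}")


def evaluate_cassette(p: CircuitParameters, step: StepExperiment,
                      thresholds: Thresholds = Thresholds()) -> AdaptationResult:
    """Simulate one cassette's step response and classify it.

    Integration failures are recorded in the result (``failed=True``,
    non-responsive, non-adapting) rather than raised, so that a screen never
    silently drops cassettes.
    """
    try:
        stepped, control = simulate_step(step, p)
        return evaluate_step_response(stepped, control,
                                      tail_n=thresholds.tail_n,
                                      sens_min=thresholds.sens_min,
                                      aerr_max=thresholds.aerr_max)
    except (SteadyStateError, SimulationError, ValueError) as exc:
        return AdaptationResult(output1=np.nan, output2=np.nan, aerr=np.nan,
                                peak_value=np.nan, peak_fold=np.nan,
                                peak_time=np.nan, adapts=False,
                                responsive=False, failed=True,
                                failure_reason=str(exc))


@dataclass
class ScanReport:
    """Aggregated screen outcome over one variant.

    ``fraction_adapting`` is the adapting fraction *among responsive*
    cassettes (cassettes whose input-drive parameters give no stimulus at
    all carry no information about adaptation).  Every cassette falls into
    exactly one class: failed, non-responsive, responsive-non-adapting or
    responsive-adapting.
    """

    variant: str
    n_samples: int
    n_responsive: int
    n_adapting: int
    n_failed: int
    fraction_adapting: float
    records: List[dict]
    thresholds: Thresholds
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds"] = asdict(self.thresholds)
        return d


def scan_cassettes(cassettes: Sequence[CircuitParameters], variant: str,
                   step: StepExperiment = DEFAULT_SCAN_STEP,
                   thresholds: Thresholds = Thresholds(),
                   c_pf_multiple: float = 1.0,
                   seed: Optional[int] = None,
                   max_failed_fraction: float = 0.05) -> ScanReport:
    """Evaluate a fixed cassette list under one variant and aggregate.

    Aborts with a diagnostic if more than ``max_failed_fraction`` of the
    cassettes fail to converge (a symptom of pathological sampling ranges).
    """
    records = []
    n_resp = n_adapt = n_failed = 0
    for i, p in enumerate(cassettes):
        try:
            pv = apply_variant(p, variant, step.input_initial, c_pf_multiple)
            res = evaluate_cassette(pv, step, thresholds)
        except (SteadyStateError, SimulationError) as exc:
            res = AdaptationResult(np.nan, np.nan, np.nan, np.nan, np.nan,
                                   np.nan, adapts=False, responsive=False,
                                   failed=True, failure_reason=str(exc))
        if res.failed:
            n_failed += 1
        else:
            n_resp += res.responsive
            n_adapt += res.adapts
        records.append({"cassette": i, "parameters": p.to_dict(),
                        **res.to_dict()})
    n = len(cassettes)
    if n_failed > max_failed_fraction * n:
        raise RuntimeError(
            f"{n_failed}/{n} cassettes failed to converge; "
            "check the sampling ranges (rates and affinities may be too extreme)")
    frac = n_adapt / n_resp if n_resp else 0.0
    return ScanReport(variant=variant, n_samples=n, n_responsive=n_resp,
                      n_adapting=n_adapt, n_failed=n_failed,
                      fraction_adapting=frac, records=records,
                      thresholds=thresholds, seed=seed)


def scan_topology(ranges: ParameterRanges, variant: str = "full",
                  step: StepExperiment = DEFAULT_SCAN_STEP,
                  thresholds: Thresholds = Thresholds(),
                  c_pf_multiple: float = 1.0) -> ScanReport:
    """Sample cassettes from ``ranges`` and screen them under ``variant``."""
    cassettes = sample_parameters(ranges)
    return scan_cassettes(cassettes, variant, step, thresholds,
                          c_pf_multiple, seed=ranges.seed)


def _analytic_regime_prescreen(p: CircuitParameters, inp: float,
                               max_b_frac: float, min_leak_fold: float,
                               margin: float = 2.0) -> bool:
    """Cheap closed-form screen for the weak-linear regime conditions.

    Uses the ideal-limit balance (rep* = gammaB*K_BB/alpha2, A* from the
    repression inverse, B* from the activation inverse) with a slack
    ``margin`` on every inequality, so that no cassette the exact ODE-based
    check would accept is rejected here.  Orders of magnitude faster than
    integrating, which makes rejection sampling of the restricted screen
    tractable.
    """
    from .circuit_model import hill_repression, input_drive

    rep_req = p.gammaB * p.K_BB / p.alpha2  # required repression factor
    rep_hill = rep_req - p.beta_AB
    if not (min_leak_fold * p.beta_AB / margin < rep_hill < min(0.9 * margin, 1.0)):
        return False
    A_star = p.K_AB * (1.0 / rep_hill - 1.0) ** (1.0 / p.n_AB)
    act_req = A_star * p.gammaA / (p.alpha1 * input_drive(inp, p))
    act_hill = act_req - p.beta_BA
    if not (min_leak_fold * p.beta_BA / margin < act_hill < min(0.95 * margin, 1.0)):
        return False
    B_star = p.K_BA * (act_hill / (1.0 - act_hill)) ** (1.0 / p.n_BA)
    if B_star > margin * max_b_frac * p.K_BB:
        return False
    s_hill = B_star ** p.n_BB / (p.K_BB ** p.n_BB + B_star ** p.n_BB)
    if s_hill * margin < min_leak_fold * p.beta_BB:
        return False
    return True


def weak_linear_regime(p: CircuitParameters, inputs=(2.0, 200.0),
                       max_b_frac: float = 0.05,
                       min_leak_fold: float = 10.0) -> bool:
    """True when a cassette operates in the weak-linear-feedback regime.

    At every input in ``inputs`` (typically both step endpoints) the steady
    state must (i) admit an interior adaptive balance
    (``alpha2 > gammaB * K_BB``), (ii) operate weakly,
    ``B <= max_b_frac * K_BB``, and (iii) sit on the self-activated branch
    rather than the leak floor: the Hill part of the self-activation factor
    must exceed ``min_leak_fold`` times the leak ``beta_BB``.  Collapsed
    circuits (B decayed to leak-supported residual expression) satisfy the
    weakness bound trivially but carry no feedback, so (iii) excludes them.
    Cassettes whose pre-equilibration fails are excluded.
    """
    if p.alpha2 <= p.gammaB * p.K_BB:
        return False
    inputs = np.atleast_1d(inputs)
    if not all(_analytic_regime_prescreen(p, float(i), max_b_frac,
                                          min_leak_fold) for i in inputs):
        return False
    for inp in inputs:
        try:
            ss = steady_state(float(inp), p)
        except SteadyStateError:
            return False
        if ss.B > max_b_frac * p.K_BB:
            return False
        s_hill = float(p.self_activation(ss.B)) - p.beta_BB
        if s_hill < min_leak_fold * p.beta_BB:
            return False
        # The feedback loop must actually be closed: each internal edge has
        # to operate in its responsive range, neither pinned at its leak
        # (edge effectively deleted) nor saturated (zero gain).
        act_hill = float(p.activation(ss.B)) - p.beta_BA
        if act_hill < min_leak_fold * p.beta_BA or act_hill > 0.95:
            return False
        rep_hill = float(p.repression(ss.A)) - p.beta_AB
        if rep_hill < min_leak_fold * p.beta_AB or rep_hill > 0.9:
            return False
    return True


def sample_restricted(ranges: ParameterRanges, predicate,
                      max_draw_factor: int = 100) -> List[CircuitParameters]:
    """Rejection-sample ``ranges.n_samples`` cassettes satisfying ``predicate``.

    Draws batches from the same stream (deterministic given ``ranges.seed``)
    until enough cassettes pass, e.g. :func:`weak_linear_regime` for the
    restricted analytic-regime screen.  Raises if the acceptance rate is so
    low that ``max_draw_factor * n_samples`` draws do not suffice.
    """
    accepted: List[CircuitParameters] = []
    drawn = 0
    batch = ParameterRanges(ranges.ranges, ranges.fixed,
                            n_samples=max(ranges.n_samples, 50),
                            seed=ranges.seed)
    rng_seed = ranges.seed
    while len(accepted) < ranges.n_samples:
        if drawn > max_draw_factor * ranges.n_samples:
            raise RuntimeError(
                f"restricted sampling accepted only {len(accepted)} of {drawn} "
                "draws; the predicate region is too small for these ranges")
        batch = ParameterRanges(ranges.ranges, ranges.fixed,
                                n_samples=batch.n_samples, seed=rng_seed)
        for p in sample_parameters(batch):
            drawn += 1
            if predicate(p):
                accepted.append(p)
                if len(accepted) == ranges.n_samples:
                    break
        rng_seed += 104729  # disjoint stream per batch, still seed-determined
    return accepted


def edge_perturbation_sweep(p: CircuitParameters, edge: str,
                            fold_factors: Sequence[float],
                            step: StepExperiment,
                            thresholds: Thresholds = Thresholds()
                            ) -> List[AdaptationResult]:
    """Scale one regulatory edge by each fold factor and evaluate adaptation.

    ``self_activation`` scales the buffer self-production (equivalently
    alpha2, promoter-strength mutants of the self-activating promoter);
    ``B_to_A`` scales alpha1 (activation-strength mutants); ``A_to_B``
    scales K_AB (altered guide-RNA targeting efficiency).
    """
    if edge not in EDGES:
        raise ValueError(f"unknown edge {edge!r}; expected one of {EDGES}")
    if np.any(np.asarray(fold_factors, dtype=float) <= 0):
        raise ValueError("fold factors must be positive")
    out = []
    for f in fold_factors:
        if edge == "self_activation":
            q = p.with_updates(alpha2=p.alpha2 * f)
        elif edge == "B_to_A":
            q = p.with_updates(alpha1=p.alpha1 * f)
        else:
            q = p.with_updates(K_AB=p.K_AB * f)
        out.append(evaluate_cassette(q, step, thresholds))
    return out
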