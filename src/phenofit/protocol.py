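"""Simulation-and-classification protocol: parameter vector -> phenotype calls.

The viability rules follow the standard in-silico genetics screen for
growing-and-dividing cell models:

* simulate for a fixed horizon (default 2000 min) with fixed-step forward
  Euler (default dt = 0.05 min);
* if cell mass ever exceeds the mass limit (default 25 units) the cell has
  arrested and keeps growing: *inviable* (simulation stops there);
* otherwise the cell is *viable* if it divided at least three times and the
  size at the last division is within the tolerance (default 5%, relative to
  the earlier size) of the sizes at EACH of the two previous divisions;
* a last size that disagrees with the previous division but matches the one
  before that is the signature of period-doubled divisions: *indeterminate*
  (matches neither observed phenotype), as is any run with too few divisions
  and no blow-up.

The per-strain objective is the integer number of strains whose call equals
the observed phenotype.  Mutant simulations all start from the "newborn"
state recorded just after the wild type's last division (or from configured
default initial conditions when the wild type itself is not viable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .model import SimulationTrace, StrainModel
from .parameters import (
    ParameterVector,
    StrainSpec,
    apply_compiled,
    compile_transformations,
)

logger = logging.getLogger(__name__)

VIABLE = "viable"
INVIABLE = "inviable"
INDETERMINATE = "indeterminate"

__all__ = [
    "PhenotypeCall",
    "ProtocolSettings",
    "ObjectiveResult",
    "simulate_strain",
    "classify_viability",
    "wt_bootstrap",
    "evaluate_objective",
    "check_event_order",
    "VIABLE",
    "INVIABLE",
    "INDETERMINATE",
]


@dataclass(frozen=True)
class PhenotypeCall:
    """A viability call plus the rule that produced it."""

    call: str  # viable | inviable | indeterminate
    reason: str  # mass_blowup | numerical_failure | size_converged |
    #              period_doubling | insufficient_divisions

    def matches(self, observed: str) -> bool:
        """Indicator semantics: indeterminate matches nothing."""
        return self.call == observed


@dataclass(frozen=True)
class ProtocolSettings:
    """Numerical settings of the viability protocol."""

    horizon: float = 2000.0  # minutes
    dt: float = 0.05  # minutes
    mass_limit: float = 25.0  # mass units
    size_tolerance: float = 0.05  # relative tolerance of the division-size rule
    min_divisions: int = 3  # the size rule needs a last and two previous sizes
    default_ics: Optional[np.ndarray] = None  # fallback when WT is inviable
    use_fast_path: bool = True  # use the model's compiled integrator if any

    def __post_init__(self) -> None:
        if self.horizon <= 0 or self.dt <= 0:
            raise ValueError("horizon and dt must be positive")
        if not 0 < self.size_tolerance < 1:
            raise ValueError("size_tolerance must lie in (0, 1)")


def simulate_strain(
    model: StrainModel,
    params: np.ndarray | ParameterVector,
    ics: np.ndarray,
    settings: ProtocolSettings,
    record: bool = False,
) -> SimulationTrace:
    """Forward-simulate one strain over [0, horizon].

    Stops early the first time mass exceeds the limit (blow-up flag) or the
    state leaves the finite domain (flagged, never raised).  Dispatches to
    the model's compiled integrator when available unless ``record`` or
    ``settings.use_fast_path=False`` force the generic stepping path.
    """
    values = params.values if isinstance(params, ParameterVector) else np.asarray(params, float)
    ics = np.asarray(ics, dtype=float)
    if model.simulate is not None and settings.use_fast_path and not record:
        return model.simulate(values, ics, settings)
    return _simulate_generic(model, values, ics, settings, record)


def _simulate_generic(
    model: StrainModel,
    params: np.ndarray,
    ics: np.ndarray,
    settings: ProtocolSettings,
    record: bool,
) -> SimulationTrace:
    """Reference integration loop over the model's one-step contract."""
    dt = settings.dt
    n_steps = int(round(settings.horizon / dt))
    threshold = model.division_threshold(params)
    events = model.events(params)

    state = ics.copy()
    t = 0.0
    signal = model.division_signal(state)
    ev_signals = [ev.signal(state) for ev in events]

    div_times: list[float] = []
    div_sizes: list[float] = []
    ev_times: dict[str, list[float]] = {ev.name: [] for ev in events}
    post_div: Optional[np.ndarray] = None
    blew_up = nonfinite = False
    times = [0.0] if record else None
    masses = [model.mass_of(state)] if record else None

    for _ in range(n_steps):
        new_state = model.step(state, params, dt)
        t_new = t + dt
        if not np.all(np.isfinite(new_state)):
            nonfinite = True
            break
        for k, ev in enumerate(events):
            s_new = ev.signal(new_state)
            s_old = ev_signals[k]
            crossed = (
                s_old < ev.threshold <= s_new
                if ev.direction > 0
                else s_old > ev.threshold >= s_new
            )
            if crossed and s_new != s_old:
                frac = (ev.threshold - s_old) / (s_new - s_old)
                ev_times[ev.name].append(t + frac * dt)
            ev_signals[k] = s_new
        new_signal = model.division_signal(new_state)
        divided = False
        if signal > threshold >= new_signal and new_signal != signal:
            frac = (signal - threshold) / (signal - new_signal)
            m_old, m_new = model.mass_of(state), model.mass_of(new_state)
            div_times.append(t + frac * dt)
            div_sizes.append(m_old + frac * (m_new - m_old))
            new_state = model.divide(new_state, params)
            divided = True
        signal = model.division_signal(new_state)
        state, t = new_state, t_new
        if divided:
            post_div = state.copy()
        if record:
            times.append(t)  # type: ignore[union-attr]
            masses.append(model.mass_of(state))  # type: ignore[union-attr]
        if model.mass_of(state) > settings.mass_limit:
            blew_up = True
            break

    return SimulationTrace(
        division_times=np.asarray(div_times),
        division_sizes=np.asarray(div_sizes),
        blew_up=blew_up,
        nonfinite=nonfinite,
        t_end=t,
        final_state=state,
        post_division_state=post_div,
        event_times={k: np.asarray(v) for k, v in ev_times.items()},
        times=np.asarray(times) if record else None,
        mass_series=np.asarray(masses) if record else None,
    )


def classify_viability(trace: SimulationTrace, settings: ProtocolSettings) -> PhenotypeCall:
    """Apply the blow-up / converged-size / period-doubling rules to a trace."""
    if trace.blew_up:
        return PhenotypeCall(INVIABLE, "mass_blowup")
    if trace.nonfinite:
        return PhenotypeCall(INVIABLE, "numerical_failure")
    sizes = trace.division_sizes
    if len(sizes) < settings.min_divisions:
        return PhenotypeCall(INDETERMINATE, "insufficient_divisions")
    s_last, s_prev, s_prevprev = sizes[-1], sizes[-2], sizes[-3]
    tol = settings.size_tolerance
    near_prev = abs(s_last - s_prev) <= tol * s_prev
    near_prevprev = abs(s_last - s_prevprev) <= tol * s_prevprev
    if near_prev and near_prevprev:
        return PhenotypeCall(VIABLE, "size_converged")
    if not near_prev and near_prevprev:
        # sizes alternate between two values: period-doubled divisions
        return PhenotypeCall(INDETERMINATE, "period_doubling")
    return PhenotypeCall(INDETERMINATE, "insufficient_divisions")


def wt_bootstrap(
    model: StrainModel,
    params: np.ndarray | ParameterVector,
    settings: ProtocolSettings,
    input_ics: Optional[np.ndarray] = None,
) -> tuple[PhenotypeCall, np.ndarray]:
    """Simulate the wild type and derive initial conditions for mutants.

    A viable wild type yields the full state recorded just after its last
    division (the "newborn" state, which bears no relation to the input
    initial conditions).  If the wild type is not viable the configured
    default initial conditions are returned instead, so mutants can still be
    scored.
    """
    values = params.values if isinstance(params, ParameterVector) else np.asarray(params, float)
    if input_ics is None:
        input_ics = model.initial_state(values)
    trace = simulate_strain(model, values, input_ics, settings)
    call = classify_viability(trace, settings)
    if call.call == VIABLE and trace.post_division_state is not None:
        return call, np.asarray(trace.post_division_state, dtype=float)
    fallback = settings.default_ics if settings.default_ics is not None else model.default_ics
    return call, np.asarray(fallback, dtype=float)


@dataclass
class ObjectiveResult:
    """Outcome of scoring one parameter vector against the strain table."""

    objective: int
    bits: dict[str, int]  # strain_id -> indicator (1 = hit)
    calls: dict[str, PhenotypeCall]
    wt_call: PhenotypeCall
    bootstrap_ics: np.ndarray

    @property
    def n_strains(self) -> int:
        return len(self.bits)


class CompiledPanel:
    """Strain table with pre-resolved transformations for bulk scoring."""

    def __init__(self, model: StrainModel, strains: Optional[Sequence[StrainSpec]] = None):
        self.model = model
        self.strains = list(strains if strains is not None else model.strains)
        space = model.wt_params.space
        self._compiled = [compile_transformations(space, s) for s in self.strains]

    def mutant_values(self, values: np.ndarray, k: int) -> np.ndarray:
        idx, ops, operands = self._compiled[k]
        return apply_compiled(values, idx, ops, operands)


def evaluate_objective(
    model: StrainModel,
    params: np.ndarray | ParameterVector,
    settings: ProtocolSettings,
    selection: Optional[Sequence[str]] = None,
    panel: Optional[CompiledPanel] = None,
) -> ObjectiveResult:
    """Score a parameter vector: O = number of strains called correctly.

    Runs the wild-type bootstrap once, then simulates every strain from the
    bootstrap state with its transformed parameters.  The indicator of a
    strain is 1 iff its call equals its observed phenotype (an indeterminate
    call matches nothing); O is the sum over the selected strains (all of
    them by default).  A failing strain simulation scores 0 and is logged,
    never raised.
    """
    values = params.values if isinstance(params, ParameterVector) else np.asarray(params, float)
    if panel is None:
        panel = CompiledPanel(model)
    if not panel.strains:
        raise ValueError("strain table is empty")
    selected = None if selection is None else set(selection)

    wt_call, ics = wt_bootstrap(model, values, settings)
    bits: dict[str, int] = {}
    calls: dict[str, PhenotypeCall] = {}
    objective = 0
    for k, spec in enumerate(panel.strains):
        try:
            mutant = panel.mutant_values(values, k)
            trace = simulate_strain(model, mutant, ics, settings)
            call = classify_viability(trace, settings)
        except Exception:  # noqa: BLE001 -- a bad vector must not abort scoring
            logger.exception("simulation failed for strain %s", spec.strain_id)
            call = PhenotypeCall(INDETERMINATE, "numerical_failure")
        calls[spec.strain_id] = call
        bit = int(call.matches(spec.observed))
        bits[spec.strain_id] = bit
        if selected is None or spec.strain_id in selected:
            objective += bit
    return ObjectiveResult(objective, bits, calls, wt_call, ics)


def check_event_order(
    trace: SimulationTrace, expected: Sequence[str]
) -> tuple[bool, list[str]]:
    """Audit that cycle events occur in the expected order every cycle.

    The k-th occurrence of each expected event belongs to cycle k; within a
    cycle the occurrence times must strictly increase along the expected
    order.  Each out-of-order adjacency, each missing event name, and any
    occurrence-count mismatch produces one violation entry.
    """
    violations: list[str] = []
    for name in expected:
        if name not in trace.event_times:
            violations.append(f"event {name!r} missing from trace")
    if violations:
        return False, violations

    times = {n: np.asarray(trace.event_times[n], dtype=float) for n in expected}
    counts = {n: len(times[n]) for n in expected}
    n_cycles = min(counts.values())
    if len(set(counts.values())) > 1:
        violations.append(
            "event occurrence counts differ: "
            + ", ".join(f"{n}={c}" for n, c in counts.items())
        )
    if n_cycles == 0:
        violations.append("no completed cycles to audit")
        return False, violations
    for c in range(n_cycles):
        for a, b in zip(expected[:-1], expected[1:]):
            if times[b][c] <= times[a][c]:
                violations.append(
                    f"cycle {c + 1}: {b!r} at t={times[b][c]:g} not after "
                    f"{a!r} at t={times[a][c]:g}"
                )
    return not violations, violations
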