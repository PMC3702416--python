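"""The pluggable strain-model contract.

Any ODE model can be driven by the viability protocol and the optimizer as
long as it exposes: a wild-type parameter vector, a strain table, a
deterministic one-step integrator, a scalar division signal with a declared
threshold (division fires on a downward crossing), a division reset (the
mass partition between mother and daughter), and the cell mass of a state.

Models may additionally provide a ``simulate`` fast path (a compiled
whole-trajectory integrator); the protocol uses it when present and falls
back to generic stepping otherwise, so the two paths can be cross-checked.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .parameters import ParameterVector, StrainSpec

__all__ = ["EventDef", "SimulationTrace", "StrainModel"]


@dataclass(frozen=True)
class EventDef:
    """A named threshold-crossing event on a scalar function of the state.

    ``direction`` is +1 for an upward crossing, -1 for a downward one.
    """

    name: str
    signal: Callable[[np.ndarray], float]
    threshold: float
    direction: int


@dataclass
class SimulationTrace:
    """Outcome of one forward simulation of one strain.

    Division times are in minutes from simulation start; ``division_sizes``
    holds the cell mass at each division (before the mass partition).  The
    dense ``times``/``mass_series`` arrays are recorded only on request --
    bulk evaluation keeps traces light.
    """

    division_times: np.ndarray
    division_sizes: np.ndarray
    blew_up: bool
    nonfinite: bool
    t_end: float
    final_state: np.ndarray
    post_division_state: Optional[np.ndarray] = None
    event_times: Mapping[str, np.ndarray] = field(default_factory=dict)
    times: Optional[np.ndarray] = None
    mass_series: Optional[np.ndarray] = None

    @property
    def n_divisions(self) -> int:
        return len(self.division_times)


class StrainModel(abc.ABC):
    """Contract a model must satisfy to be optimized against phenotypes."""

    #: parameters held constant by convention (e.g. mass doubling time,
    #: daughter mass fraction); excluded from sampling and perturbation
    fixed_names: frozenset[str] = frozenset()

    @property
    @abc.abstractmethod
    def wt_params(self) -> ParameterVector:
        """Ground wild-type parameter vector (kinetics + initial conditions)."""

    @property
    @abc.abstractmethod
    def strains(self) -> Sequence[StrainSpec]:
        """The strain table: observed phenotypes and parameter transformations."""

    @property
    @abc.abstractmethod
    def default_ics(self) -> np.ndarray:
        """Fallback initial state used for mutants when WT is not viable."""

    @abc.abstractmethod
    def initial_state(self, params: np.ndarray) -> np.ndarray:
        """Input initial conditions extracted from a parameter vector."""

    @abc.abstractmethod
    def step(self, state: np.ndarray, params: np.ndarray, dt: float) -> np.ndarray:
        """One deterministic integration step (forward Euler by default)."""

    @abc.abstractmethod
    def division_signal(self, state: np.ndarray) -> float:
        """Scalar whose downward crossing of the threshold marks division."""

    @abc.abstractmethod
    def division_threshold(self, params: np.ndarray) -> float:
        """Threshold for the division signal (may itself be a parameter)."""

    @abc.abstractmethod
    def divide(self, state: np.ndarray, params: np.ndarray) -> np.ndarray:
        """Apply the model's mass partition to the state at division."""

    @abc.abstractmethod
    def mass_of(self, state: np.ndarray) -> float:
        """Cell mass of a state; nonnegative along nonnegative trajectories."""

    def events(self, params: np.ndarray) -> tuple[EventDef, ...]:
        """Declared cycle events for order-of-events audits (optional)."""
        return ()

    # models may override with a compiled fast path:
    #   simulate(params, ics, settings) -> SimulationTrace
    simulate: Optional[Callable] = None
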