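"""Shared fixtures: the bundled toy model and a tiny analytic clock model.

The clock model divides on a strict schedule (a sawtooth phase variable
falling through a threshold every ``period`` minutes) with exponentially
growing mass, so division times and sizes have closed forms and protocol
behaviour can be asserted exactly.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from phenofit.model import EventDef, StrainModel
from phenofit.parameters import (
    INITIAL_CONDITION,
    KINETIC,
    ParameterSpace,
    ParameterVector,
    StrainSpec,
)
from phenofit.protocol import ProtocolSettings
from phenofit.toymodel import make_panel, make_wt


class ClockModel(StrainModel):
    """Sawtooth phase u falling from ``period`` to 0; division when u falls
    through period/2; mass grows at rate g and is partitioned by f."""

    fixed_names = frozenset()

    def __init__(self, strains=()):
        self.space = ParameterSpace(
            ("g", "period", "f", "u0", "m0"),
            (KINETIC, KINETIC, KINETIC, INITIAL_CONDITION, INITIAL_CONDITION),
        )
        self._strains = list(strains)

    @property
    def wt_params(self) -> ParameterVector:
        # f * exp(g*period) == 1: division sizes exactly constant
        g, period = 0.01, 50.0
        return ParameterVector(
            self.space, np.array([g, period, math.exp(-g * period), 40.0, 1.0])
        )

    @property
    def strains(self):
        return list(self._strains)

    @strains.setter
    def strains(self, value):
        self._strains = list(value)

    @property
    def default_ics(self) -> np.ndarray:
        return np.array([40.0, 1.0])

    def initial_state(self, params: np.ndarray) -> np.ndarray:
        return np.asarray(params[3:], dtype=float).copy()

    def step(self, state, params, dt):
        g, period = params[0], params[1]
        u, m = state
        u = u - dt
        if u <= 0.0:
            u += period
        return np.array([u, m * math.exp(g * dt)])

    def division_signal(self, state):
        return float(state[0])

    def division_threshold(self, params):
        return float(params[1]) / 2.0

    def divide(self, state, params):
        out = state.copy()
        out[1] *= params[2]
        return out

    def mass_of(self, state):
        return float(state[1])

    def events(self, params):
        period = float(params[1])
        return (EventDef("quarter", lambda s: float(s[0]), 0.75 * period, -1),)


@pytest.fixture(scope="session")
def protocol_settings() -> ProtocolSettings:
    return ProtocolSettings()


@pytest.fixture(scope="session")
def toy_panel():
    return make_panel()


@pytest.fixture(scope="session")
def toy(toy_panel):
    """(model-with-panel, ground-truth vector) for the bundled toy model."""
    model, wt = make_wt()
    model.strains = toy_panel
    return model, wt


@pytest.fixture()
def clock_model() -> ClockModel:
    return ClockModel()


@pytest.fixture()
def tiny_space() -> ParameterSpace:
    return ParameterSpace(("k_syn", "k_deg", "c0"), (KINETIC, KINETIC, INITIAL_CONDITION))


@pytest.fixture()
def tiny_vector(tiny_space) -> ParameterVector:
    return ParameterVector(tiny_space, np.array([0.3, 1.5, 2.0]))
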