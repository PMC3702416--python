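"""A bundled toy cell-cycle model with known ground truth.

The model is a three-variable caricature of a growing-and-dividing cell:

* ``X`` -- an autocatalytic activator (a cyclin/CDK-like "division trigger"):
  synthesized in proportion to cell mass, amplified through a saturating
  positive feedback, degraded basally and, much more strongly, by the
  inhibitor;
* ``Y`` -- a slow inhibitor produced by X and decaying first-order, so it
  tracks X with a lag and eventually shuts each X pulse down;
* ``M`` -- cell mass, growing exponentially (``dM/dt = mu*M``).

    dX/dt = ks_x*M + ka_x*X^2/(J_x^2 + X^2) - (kd_x + kd_xy*Y)*X
    dY/dt = ks_y*X - kd_y*Y
    dM/dt = mu*M

Rising mass drives X past the saturable feedback's ignition point; the Y
lag then terminates the pulse.  Division fires when X falls through the
threshold ``theta_div``; the daughter keeps the fraction ``f_daughter`` of
the mother's mass.  Because ignition requires sufficient mass, the cycle is
size-controlled and division sizes converge -- the viable regime.  Breaking
the oscillator (e.g. deleting X synthesis or the positive feedback) arrests
the cell, whose mass then grows past the protocol's limit -- the inviable
regime.  Strengthening the inhibitor's efficacy moves the map into a
period-doubled regime where division sizes alternate between two values --
classified indeterminate by the protocol.

The growth rate (mass doubling time 100 min) and the daughter mass fraction
(0.4) are held fixed by convention, mirroring standard practice for this
kind of model; all other kinetic constants and the three initial conditions
are searchable.  The bundled mutant panel is labelled by running the
viability protocol at the ground-truth parameters, so the panel is
self-consistent by construction and a perfect objective score is attainable.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .model import EventDef, SimulationTrace, StrainModel
from .parameters import (
    INITIAL_CONDITION,
    KINETIC,
    ParameterSpace,
    ParameterVector,
    StrainSpec,
)
from .protocol import INDETERMINATE, ProtocolSettings, classify_viability, evaluate_objective

__all__ = [
    "ToyCellCycleModel",
    "make_wt",
    "make_panel",
    "degrade_start",
    "GROUND_TRUTH",
    "DOUBLING_REGION",
]

KIN_NAMES = (
    "ks_x",  # mass-proportional X synthesis rate          [conc/(mass*min)]
    "ka_x",  # autocatalytic X amplification rate          [conc/min]
    "J_x",  # half-saturation of the positive feedback     [conc]
    "kd_x",  # basal X degradation rate                    [1/min]
    "kd_xy",  # Y-mediated X degradation rate              [1/(conc*min)]
    "ks_y",  # X-driven Y synthesis rate                   [1/min]
    "kd_y",  # Y decay rate                                [1/min]
    "mu",  # specific mass growth rate (fixed)             [1/min]
    "f_daughter",  # daughter mass fraction at division (fixed)
    "theta_div",  # X level whose downward crossing fires division  [conc]
    "theta_start",  # X level whose upward crossing marks cycle start [conc]
)
IC_NAMES = ("x0", "y0", "m0")
ALL_NAMES = KIN_NAMES + IC_NAMES

#: ground-truth wild type: a stable limit cycle dividing every ~132 min at
#: size ~4.0 mass units (14-15 divisions in the 2000-min protocol horizon)
GROUND_TRUTH: dict[str, float] = {
    "ks_x": 0.0028,
    "ka_x": 1.0,
    "J_x": 0.38,
    "kd_x": 0.33,
    "kd_xy": 5.4,
    "ks_y": 0.07,
    "kd_y": 0.09,
    "mu": math.log(2) / 100.0,  # mass doubling time fixed at 100 min
    "f_daughter": 0.4,
    "theta_div": 0.2,
    "theta_start": 0.5,
    "x0": 0.05,
    "y0": 0.2,
    "m0": 1.2,
}

#: scaling the inhibitor's efficacy on X into this band (relative to the
#: ground-truth kd_xy) produces period-doubled division sizes at otherwise
#: wild-type parameters -- the protocol classifies them indeterminate
DOUBLING_REGION: dict[str, tuple[float, float]] = {"kd_xy": (1.40, 1.45)}

_FIXED = frozenset({"mu", "f_daughter"})

_MAX_DIV = 1024


@njit(cache=True)
def _kernel(kin, x0, y0, m0, dt, n_steps, mass_limit):  # pragma: no cover - jit
    ks_x, ka_x, J_x, kd_x, kd_xy, ks_y, kd_y, mu, f, th_d, th_s = (
        kin[0], kin[1], kin[2], kin[3], kin[4], kin[5], kin[6], kin[7], kin[8],
        kin[9], kin[10],
    )
    x, y, m = x0, y0, m0
    div_t = np.empty(_MAX_DIV)
    div_s = np.empty(_MAX_DIV)
    st_t = np.empty(_MAX_DIV)
    nd = 0
    ns = 0
    blew = False
    nonfin = False
    xd = yd = md = np.nan
    t = 0.0
    for _ in range(n_steps):
        x2 = x * x
        dx = ks_x * m + ka_x * x2 / (J_x * J_x + x2) - (kd_x + kd_xy * y) * x
        dy = ks_y * x - kd_y * y
        xn = x + dt * dx
        yn = y + dt * dy
        mn = m * (1.0 + dt * mu)
        if not (np.isfinite(xn) and np.isfinite(yn) and np.isfinite(mn)):
            nonfin = True
            break
        if x < th_s <= xn and xn != x and ns < _MAX_DIV:
            st_t[ns] = t + dt * (th_s - x) / (xn - x)
            ns += 1
        if x > th_d >= xn and xn != x:
            if nd >= _MAX_DIV:
                break
            frac = (x - th_d) / (x - xn)
            div_t[nd] = t + frac * dt
            div_s[nd] = m + frac * (mn - m)
            nd += 1
            mn = mn * f
            xd, yd, md = xn, yn, mn
        x, y, m = xn, yn, mn
        t = t + dt
        if m > mass_limit:
            blew = True
            break
    return (
        blew, nonfin, div_t[:nd].copy(), div_s[:nd].copy(), st_t[:ns].copy(),
        x, y, m, xd, yd, md, t,
    )


class ToyCellCycleModel(StrainModel):
    """The bundled toy model wired to the generic strain-model contract."""

    fixed_names = _FIXED
    state_names = ("X", "Y", "M")

    def __init__(self, panel: Optional[Sequence[StrainSpec]] = None):
        space = ParameterSpace(
            ALL_NAMES,
            tuple(KINETIC for _ in KIN_NAMES) + tuple(INITIAL_CONDITION for _ in IC_NAMES),
        )
        self._wt = ParameterVector(
            space, np.array([GROUND_TRUTH[n] for n in ALL_NAMES])
        )
        self._panel: list[StrainSpec] = list(panel) if panel is not None else []
        self._n_kin = len(KIN_NAMES)

    @property
    def wt_params(self) -> ParameterVector:
        return self._wt.copy()

    @property
    def strains(self) -> list[StrainSpec]:
        return list(self._panel)

    @strains.setter
    def strains(self, panel: Sequence[StrainSpec]) -> None:
        self._panel = list(panel)

    @property
    def default_ics(self) -> np.ndarray:
        return np.array([GROUND_TRUTH[n] for n in IC_NAMES])

    def initial_state(self, params: np.ndarray) -> np.ndarray:
        return np.asarray(params[self._n_kin :], dtype=float).copy()

    def step(self, state: np.ndarray, params: np.ndarray, dt: float) -> np.ndarray:
        ks_x, ka_x, J_x, kd_x, kd_xy, ks_y, kd_y, mu = params[:8]
        x, y, m = state
        x2 = x * x
        dx = ks_x * m + ka_x * x2 / (J_x * J_x + x2) - (kd_x + kd_xy * y) * x
        dy = ks_y * x - kd_y * y
        return np.array([x + dt * dx, y + dt * dy, m * (1.0 + dt * mu)])

    def division_signal(self, state: np.ndarray) -> float:
        return float(state[0])

    def division_threshold(self, params: np.ndarray) -> float:
        return float(params[ALL_NAMES.index("theta_div")])

    def divide(self, state: np.ndarray, params: np.ndarray) -> np.ndarray:
        out = state.copy()
        out[2] *= params[ALL_NAMES.index("f_daughter")]
        return out

    def mass_of(self, state: np.ndarray) -> float:
        return float(state[2])

    def events(self, params: np.ndarray) -> tuple[EventDef, ...]:
        th_s = float(params[ALL_NAMES.index("theta_start")])
        return (EventDef("start", lambda s: float(s[0]), th_s, +1),)

    # compiled whole-trajectory fast path used by the protocol when present
    def simulate(
        self, params: np.ndarray, ics: np.ndarray, settings: ProtocolSettings
    ) -> SimulationTrace:
        kin = np.ascontiguousarray(params[: self._n_kin], dtype=float)
        blew, nonfin, div_t, div_s, st_t, x, y, m, xd, yd, md, t_end = _kernel(
            kin,
            float(ics[0]),
            float(ics[1]),
            float(ics[2]),
            settings.dt,
            int(round(settings.horizon / settings.dt)),
            settings.mass_limit,
        )
        post = None if math.isnan(md) else np.array([xd, yd, md])
        return SimulationTrace(
            division_times=div_t,
            division_sizes=div_s,
            blew_up=bool(blew),
            nonfinite=bool(nonfin),
            t_end=t_end,
            final_state=np.array([x, y, m]),
            post_division_state=post,
            event_times={"start": st_t, "division": div_t},
        )


def make_wt() -> tuple[ToyCellCycleModel, ParameterVector]:
    """Deterministically construct the toy model and its ground-truth vector."""
    model = ToyCellCycleModel()
    return model, model.wt_params


#: the fixed mutant panel: (strain_id, transformation tokens).  Deletions
#: zero a rate, overexpression scales it, point mutants set an absolute
#: value.  Labels are computed from the ground truth by the protocol.
_PANEL_DEFS: tuple[tuple[str, str], ...] = (
    ("WT_reference", ""),
    ("WT_rich_medium", "ks_x=*1.3"),
    ("actsyn-del", "ks_x=0"),
    ("actsyn-hypo", "ks_x=*0.3"),
    ("actsyn-OE", "ks_x=*3"),
    ("autocat-del", "ka_x=0"),
    ("autocat-hypo", "ka_x=*0.9"),
    ("autocat-weak", "ka_x=*0.6"),
    ("autocat-OE", "ka_x=*2"),
    ("autocat-low-edge", "ka_x=*0.82"),
    ("autocat-high-edge", "ka_x=*1.38"),
    ("feedback-sat-low-edge", "J_x=*0.87"),
    ("feedback-sat-high-edge", "J_x=*1.07"),
    ("feedback-sat-high", "J_x=*1.3"),
    ("inhib-eff-low-edge", "kd_xy=*0.72"),
    ("inhib-eff-high-edge", "kd_xy=*1.27"),
    ("inhibsyn-low-edge", "ks_y=*0.72"),
    ("inhibsyn-high-edge", "ks_y=*1.27"),
    ("inhibdeg-low-edge", "kd_y=*0.62"),
    ("inhibdeg-high-edge", "kd_y=*1.45"),
    ("basal-deg-del", "kd_x=0"),
    ("basal-deg-OE", "kd_x=*2"),
    ("basal-deg-strong", "kd_x=*3.5"),
    ("inhib-eff-hypo", "kd_xy=*0.6"),
    ("inhib-eff-mild", "kd_xy=*0.9"),
    ("inhib-eff-OE", "kd_xy=*2.2"),
    ("inhibsyn-del", "ks_y=0"),
    ("inhibsyn-OE", "ks_y=*1.25"),
    ("inhibsyn-strong", "ks_y=*2.5"),
    ("inhibdeg-hypo", "kd_y=*0.65"),
    ("inhibdeg-OE", "kd_y=*2"),
    ("divthresh-low", "theta_div==0.1"),
    ("divthresh-high", "theta_div=*2.5"),
    ("ic-mass-large", "m0==8"),
)


def make_panel(
    seed: Optional[int] = None,
    n_extra: int = 0,
    settings: Optional[ProtocolSettings] = None,
) -> list[StrainSpec]:
    """Build the toy strain panel, labelled by the protocol at ground truth.

    The fixed panel covers deletion, hypomorph, overexpression and point
    mutants of every pathway arm, both wild-type growth conditions, a
    dispensable initial-condition mutant, and a competitive pair
    (``autocat-low-edge`` / ``autocat-high-edge``) whose correct calls pull
    the autocatalysis rate in opposite directions.  ``n_extra`` appends
    seeded random single-parameter scale mutants.  Every observed label
    equals the protocol's call at ground truth (strains whose ground-truth
    call is indeterminate are excluded), so the panel is self-consistent and
    the maximum objective equals its length.
    """
    if settings is None:
        settings = ProtocolSettings()
    model, wt = make_wt()

    defs = [StrainSpec.from_tokens(sid, "viable", toks) for sid, toks in _PANEL_DEFS]
    if n_extra:
        rng = np.random.default_rng(seed)
        searchable = [n for n in KIN_NAMES if n not in _FIXED]
        k = 0
        while k < n_extra:
            name = searchable[int(rng.integers(len(searchable)))]
            factor = float(np.exp(rng.uniform(np.log(0.3), np.log(2.5))))
            defs.append(
                StrainSpec.from_tokens(f"rand-{k}-{name}", "viable", f"{name}=*{factor:.4g}")
            )
            k += 1

    model.strains = defs
    result = evaluate_objective(model, wt, settings)
    panel = []
    for spec in defs:
        call = result.calls[spec.strain_id]
        if call.call == INDETERMINATE:
            if spec.strain_id.startswith("rand-"):
                continue  # random draws may land in the indeterminate regime
            raise RuntimeError(
                f"fixed panel strain {spec.strain_id} is indeterminate at ground truth"
            )
        panel.append(StrainSpec(spec.strain_id, call.call, spec.transformations))
    return panel


def degrade_start(
    ground_truth: ParameterVector, fraction: float, seed: int
) -> ParameterVector:
    """Randomly worsen a parameter vector to emulate a mediocre initial guess.

    Every non-fixed parameter is multiplied by an independent uniform factor
    in [1-fraction, 1+fraction]; reproducible from the seed.
    """
    if not 0 < fraction <= 0.9:
        raise ValueError("fraction must lie in (0, 0.9]")
    rng = np.random.default_rng(seed)
    out = ground_truth.values.copy()
    for i, name in enumerate(ground_truth.space.names):
        factor = rng.uniform(1.0 - fraction, 1.0 + fraction)
        if name not in _FIXED:
            out[i] *= factor
    return ParameterVector(ground_truth.space, out)
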