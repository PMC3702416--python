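"""Differential evolution over named parameter vectors with an integer objective.

The evolution loop is the classic DE/rand-difference scheme with one
offspring per parent per generation:

* mutation:   v_j = x_j + F * (x_j' - x_j''), with the two co-parents drawn
  uniformly without replacement from the other lineages (all three parents
  distinct) and F conservative by default (0.1);
* crossover:  u_ij = v_ij if rand(0,1) <= C else x_ij, componentwise with
  C = 0.5 by default so neither parent nor mutant is favoured (no forced
  crossover index: an offspring may equal its parent);
* selection:  greedy (offspring replaces parent only on a strictly better
  objective) or non-greedy (on at-least-equal objective).

Negative components after mutation are clamped to 0 (rate constants and
amounts are nonnegative); parameters declared fixed by the model are never
touched.  Offspring are not confined to the initial sampling hypercube.

Every parent and offspring ever evaluated is archived with its full
per-strain outcome bits, so acceptance-ratio and competition analyses can
be run afterwards without re-simulating.  The random stream is a single
seeded generator with sub-streams derived per (generation, lineage), making
runs bit-exactly reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import StrainModel
from .parameters import ParameterVector
from .protocol import CompiledPanel, ProtocolSettings, evaluate_objective
from .sampling import Hypercube, lh_sample

logger = logging.getLogger(__name__)

GREEDY = "greedy"
NON_GREEDY = "non_greedy"

__all__ = [
    "DESettings",
    "DEResult",
    "mutate",
    "crossover",
    "select",
    "run_de",
    "resample_restart",
    "best_member",
    "GREEDY",
    "NON_GREEDY",
]

HIT_PREFIX = "hit:"


@dataclass(frozen=True)
class DESettings:
    """Knobs of one DE run."""

    N: int  # population size (>= 4: parent plus three distinct co-parents)
    generations: int
    F: float = 0.1  # difference scale factor
    C: float = 0.5  # crossover probability
    selection: str = GREEDY
    selection_strains: Optional[tuple[str, ...]] = None  # None = all strains
    seed: int = 0
    #: stop after any generation whose population contains a member with at
    #: least this FULL-panel objective (None = always run all generations);
    #: the best-so-far trace is unaffected, later generations cannot improve
    #: on an attained maximum
    early_stop_full: Optional[int] = None

    def __post_init__(self) -> None:
        if self.N < 4:
            raise ValueError("population size must be >= 4")
        if not 0 < self.F < 1:
            raise ValueError("F must lie in (0, 1)")
        if not 0 <= self.C <= 1:
            raise ValueError("C must lie in [0, 1]")
        if self.selection not in (GREEDY, NON_GREEDY):
            raise ValueError(f"unknown selection rule {self.selection!r}")


def _rng_for(seed: int, generation: int, lineage: int) -> np.random.Generator:
    """Sub-stream for one (generation, lineage) cell of the run."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(generation, lineage)))


def mutate(
    x_j: np.ndarray,
    x_jp: np.ndarray,
    x_jpp: np.ndarray,
    F: float,
    frozen_idx: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Difference mutation v = x_j + F*(x_j' - x_j''), clamped at 0."""
    v = x_j + F * (x_jp - x_jpp)
    np.maximum(v, 0.0, out=v)
    if frozen_idx is not None and len(frozen_idx):
        v[frozen_idx] = x_j[frozen_idx]
    return v


def crossover(
    x_j: np.ndarray, v_j: np.ndarray, C: float, rng: np.random.Generator
) -> np.ndarray:
    """Componentwise crossover: take the mutant value where rand(0,1) <= C."""
    draws = rng.uniform(size=len(x_j))
    return np.where(draws <= C, v_j, x_j)


def select(o_parent: int, o_offspring: int, rule: str) -> bool:
    """True iff the offspring replaces its parent under the rule."""
    if rule == GREEDY:
        return o_offspring > o_parent
    if rule == NON_GREEDY:
        return o_offspring >= o_parent
    raise ValueError(f"unknown selection rule {rule!r}")


@dataclass
class DEResult:
    population: list[ParameterVector]
    archive: pd.DataFrame
    trace: pd.DataFrame  # per generation: best selection-objective and full-panel O

    @property
    def best_objective(self) -> int:
        return int(self.trace["best_O_sel"].iloc[-1])


def _evaluate(model, values, settings, selection, panel):
    try:
        return evaluate_objective(model, values, settings, selection=selection, panel=panel)
    except Exception:  # noqa: BLE001 -- a pathological vector scores 0
        logger.exception("objective evaluation failed; scoring 0")
        return None


def run_de(
    population: Sequence[ParameterVector],
    model: StrainModel,
    settings: DESettings,
    protocol: ProtocolSettings,
) -> DEResult:
    """Evolve a population, archiving every vector with full outcome bits.

    Selection compares objectives computed on ``settings.selection_strains``
    (all strains if unset); archived rows always carry the outcome bits of
    the FULL strain table so later analyses can re-score on any subset.
    """
    if len(population) != settings.N:
        raise ValueError(f"population size {len(population)} != N = {settings.N}")
    space = population[0].space
    frozen_idx = np.array(
        sorted(space.index(n) for n in model.fixed_names if n in space), dtype=np.int64
    )
    panel = CompiledPanel(model)
    strain_ids = [s.strain_id for s in panel.strains]
    selection = settings.selection_strains

    pop = np.vstack([v.values for v in population]).astype(float)
    rows: list[dict] = []

    def score(values: np.ndarray) -> tuple[int, int, dict[str, int]]:
        res = _evaluate(model, values, protocol, selection, panel)
        if res is None:
            return 0, 0, {sid: 0 for sid in strain_ids}
        return res.objective, sum(res.bits.values()), res.bits

    def record(gen, lineage, role, values, o_sel, o_full, bits, accepted):
        row = {
            "generation": gen,
            "lineage": lineage,
            "role": role,
            "accepted": accepted,
            "O_sel": o_sel,
            "O_full": o_full,
        }
        row.update({name: val for name, val in zip(space.names, values)})
        row.update({HIT_PREFIX + sid: b for sid, b in bits.items()})
        rows.append(row)

    o_sel = np.empty(settings.N, dtype=int)
    o_full = np.empty(settings.N, dtype=int)
    bits_cache: list[dict[str, int]] = [None] * settings.N  # type: ignore[list-item]
    for j in range(settings.N):
        o_sel[j], o_full[j], bits_cache[j] = score(pop[j])
        record(0, j, "parent", pop[j], o_sel[j], o_full[j], bits_cache[j], None)

    trace_rows = [
        {"generation": 0, "best_O_sel": int(o_sel.max()), "best_O_full": int(o_full[o_sel.argmax()])}
    ]
    stop = settings.early_stop_full
    for t in range(1, settings.generations + 1):
        if stop is not None and o_full.max() >= stop:
            break
        for j in range(settings.N):
            rng = _rng_for(settings.seed, t, j)
            others = np.array([k for k in range(settings.N) if k != j])
            jp, jpp = rng.choice(others, size=2, replace=False)
            v = mutate(pop[j], pop[jp], pop[jpp], settings.F, frozen_idx)
            u = crossover(pop[j], v, settings.C, rng)
            o_sel_u, o_full_u, bits_u = score(u)
            accepted = select(int(o_sel[j]), o_sel_u, settings.selection)
            record(t, j, "offspring", u, o_sel_u, o_full_u, bits_u, accepted)
            if accepted:
                pop[j] = u
                o_sel[j], o_full[j], bits_cache[j] = o_sel_u, o_full_u, bits_u
            record(t, j, "parent", pop[j], o_sel[j], o_full[j], bits_cache[j], None)
        jbest = int(o_sel.argmax())
        trace_rows.append(
            {"generation": t, "best_O_sel": int(o_sel.max()), "best_O_full": int(o_full[jbest])}
        )

    archive = pd.DataFrame(rows)
    archive["accepted"] = archive["accepted"].astype("boolean")
    archive.attrs["param_names"] = list(space.names)
    archive.attrs["param_roles"] = {n: r for n, r in zip(space.names, space.roles)}
    archive.attrs["strain_ids"] = strain_ids
    archive.attrs["frozen"] = sorted(model.fixed_names)
    trace = pd.DataFrame(trace_rows)
    final = [ParameterVector(space, row.copy()) for row in pop]
    return DEResult(final, archive, trace)


def best_member(archive: pd.DataFrame, generation: int) -> tuple[ParameterVector, int]:
    """Best parent at a generation (ties broken by lowest lineage index)."""
    from .parameters import ParameterSpace

    sub = archive[(archive["generation"] == generation) & (archive["role"] == "parent")]
    if sub.empty:
        raise ValueError(f"archive has no parent rows at generation {generation}")
    sub = sub.sort_values(["O_sel", "lineage"], ascending=[False, True], kind="stable")
    row = sub.iloc[0]
    names = archive.attrs["param_names"]
    roles = archive.attrs["param_roles"]
    space = ParameterSpace(tuple(names), tuple(roles[n] for n in names))
    vec = ParameterVector(space, row[names].to_numpy(dtype=float))
    return vec, int(row["O_sel"])


def resample_restart(
    archive: pd.DataFrame, generation: int, fraction: float, n: int, seed: int
) -> list[ParameterVector]:
    """Restart strategy: Latin-hypercube resampling around the current best.

    Takes the best population member at ``generation``, builds a ±fraction
    hypercube around it (frozen names from the archive metadata keep their
    values), and returns n fresh LH samples as the next population.
    """
    center, _ = best_member(archive, generation)
    frozen = frozenset(archive.attrs.get("frozen", ()))
    cube = Hypercube(center=center, fraction=fraction, frozen=frozen)
    return lh_sample(cube, n, seed)
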