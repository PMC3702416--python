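"""Reusable study workflows on the bundled toy model.

These functions wire the pieces together the way the framework is meant to
be used on a real model, at a scale that runs in minutes on one CPU:

1. degrade the ground truth into a mediocre "initial guess";
2. Latin-hypercube sample a fractional cube around it and keep vectors that
   reproduce wild-type viability;
3. evolve the population with DE and an integer phenotype objective;
4. analyze archives: acceptance ratios, competition, selection on a reduced
   phenotype subset, restarts, sensitivity.

Default experimental conditions: 100 LH samples in a ±40% cube, population
N = 19, F = 0.1, C = 0.5, non-greedy selection, up to 300 generations, a
degraded start with ±50% multiplicative parameter noise.  Runs stop early
once some population member captures the whole panel (the attained optimum
cannot be improved).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .competition import acceptance_from_archive, competition_profile, least_competitive_subset
from .evolve import NON_GREEDY, DEResult, DESettings, run_de
from .parameters import ParameterVector, StrainSpec
from .protocol import ProtocolSettings, evaluate_objective
from .sampling import Hypercube, filter_by_constraint, lh_sample
from .toymodel import ToyCellCycleModel, degrade_start, make_panel, make_wt

__all__ = [
    "RecoveryRun",
    "seed_population",
    "recovery_run",
    "cube_size_comparison",
    "subset_acceleration",
    "toy_setup",
]

N_POPULATION = 19
N_LH_SAMPLES = 100
DEGRADE_FRACTION = 0.5
GENERATIONS = 300


def toy_setup(
    panel: Optional[Sequence[StrainSpec]] = None,
    settings: Optional[ProtocolSettings] = None,
) -> tuple[ToyCellCycleModel, ParameterVector, ProtocolSettings]:
    """Toy model with its labelled panel, ground truth and protocol settings."""
    settings = settings or ProtocolSettings()
    model, wt = make_wt()
    model.strains = list(panel) if panel is not None else make_panel(settings=settings)
    return model, wt, settings


def seed_population(
    model: ToyCellCycleModel,
    center: ParameterVector,
    fraction: float,
    n_samples: int,
    n_population: int,
    seed: int,
    settings: ProtocolSettings,
) -> tuple[list[ParameterVector], int]:
    """LH-sample a cube and select the starting population.

    Keeps the first ``n_population`` WT-viable samples; if fewer pass the
    filter the population is topped up with rejected samples in sampling
    order, so the run can still proceed.  Returns (population, kept count).
    """
    cube = Hypercube(center=center, fraction=fraction, frozen=frozenset(model.fixed_names))
    samples = lh_sample(cube, n_samples, seed=seed)
    kept, rejected = filter_by_constraint(samples, model, settings)
    population = (kept + rejected)[:n_population]
    return population, len(kept)


@dataclass
class RecoveryRun:
    """One end-to-end optimization from a degraded start."""

    start_objective: int
    n_kept: int
    result: DEResult
    n_strains: int

    @property
    def best_full(self) -> int:
        """Best full-panel objective attained at any generation."""
        return int(self.result.trace["best_O_full"].max())

    @property
    def final_full(self) -> int:
        """Best full-panel objective in the final population."""
        last_gen = self.result.archive["generation"].max()
        parents = self.result.archive[
            (self.result.archive["generation"] == last_gen)
            & (self.result.archive["role"] == "parent")
        ]
        return int(parents["O_full"].max())

    def first_generation_reaching(self, threshold: int) -> Optional[int]:
        tr = self.result.trace
        hit = tr[tr["best_O_full"] >= threshold]
        return None if hit.empty else int(hit["generation"].iloc[0])


def recovery_run(
    seed: int,
    fraction: float = 0.4,
    generations: int = GENERATIONS,
    selection: str = NON_GREEDY,
    selection_strains: Optional[tuple[str, ...]] = None,
    degrade_fraction: float = DEGRADE_FRACTION,
    panel: Optional[Sequence[StrainSpec]] = None,
    early_stop: bool = True,
    early_stop_at: Optional[int] = None,
) -> RecoveryRun:
    """Degrade -> LH sample -> filter -> DE, under the default conditions.

    All randomness (degradation, sampling, evolution) derives from ``seed``
    via fixed offsets, so a run is one integer.
    """
    model, wt, settings = toy_setup(panel=panel)
    n = len(model.strains)
    start = degrade_start(wt, degrade_fraction, seed=seed + 1000)
    start_obj = evaluate_objective(model, start, settings).objective
    population, n_kept = seed_population(
        model, start, fraction, N_LH_SAMPLES, N_POPULATION, seed + 2000, settings
    )
    de = DESettings(
        N=N_POPULATION,
        generations=generations,
        F=0.1,
        C=0.5,
        selection=selection,
        selection_strains=selection_strains,
        seed=seed,
        early_stop_full=(early_stop_at if early_stop_at is not None else n)
        if early_stop
        else None,
    )
    result = run_de(population, model, de, settings)
    return RecoveryRun(start_obj, n_kept, result, n)


def cube_size_comparison(
    seeds: Sequence[int], fractions: tuple[float, float] = (0.2, 0.4)
) -> pd.DataFrame:
    """Paired-seed comparison of LH cube sizes (same degraded start & seeds).

    Returns one row per (seed, fraction) with the start objective and the
    best full-panel objective attained within the generation budget.
    """
    rows = []
    for seed in seeds:
        for fraction in fractions:
            run = recovery_run(seed, fraction=fraction)
            rows.append(
                {
                    "seed": seed,
                    "fraction": fraction,
                    "start_objective": run.start_objective,
                    "n_kept": run.n_kept,
                    "best_full": run.best_full,
                    "final_full": run.final_full,
                    "n_strains": run.n_strains,
                }
            )
    return pd.DataFrame(rows)


def subset_acceleration(
    seeds: Sequence[int], drop_fraction: float = 0.25, rank_seed: int = 0
) -> pd.DataFrame:
    """Competition-guided phenotype dropping, paired against full selection.

    The least-competitive phenotypes are ranked once from a small LH sample
    archive (acceptance bits of 100 cube samples around the degraded start),
    the worst ``drop_fraction`` of them are removed from the selection
    objective, and paired DE runs (same seeds) compare final full-panel
    performance with and without the reduction.
    """
    model, wt, settings = toy_setup()
    n = len(model.strains)
    start = degrade_start(wt, DEGRADE_FRACTION, seed=rank_seed + 1000)
    cube = Hypercube(center=start, fraction=0.4, frozen=frozenset(model.fixed_names))
    samples = lh_sample(cube, N_LH_SAMPLES, seed=rank_seed + 3000)

    from .evolve import HIT_PREFIX  # local to avoid cycle at import time

    bit_rows = []
    for v in samples:
        res = evaluate_objective(model, v, settings)
        bit_rows.append({HIT_PREFIX + sid: b for sid, b in res.bits.items()})
    acc = acceptance_from_archive(pd.DataFrame(bit_rows))
    profile = competition_profile(acc, provenance="lh-samples")
    k = int(round(drop_fraction * n))
    drop, keep = least_competitive_subset(profile.rhat, k)

    rows = []
    for seed in seeds:
        for label, selection in (("full", None), ("subset", tuple(keep))):
            run = recovery_run(seed, selection_strains=selection)
            rows.append(
                {
                    "seed": seed,
                    "arm": label,
                    "n_selection": n if selection is None else len(selection),
                    "best_full": run.best_full,
                    "final_full": run.final_full,
                    "n_strains": n,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["dropped"] = drop
    return out
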