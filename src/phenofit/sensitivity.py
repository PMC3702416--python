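"""Single-parameter perturbation analysis around elite vectors.

Around each of a handful of high-scoring ("elite") parameter vectors, every
varying parameter is perturbed one at a time over a fixed ladder of levels
(default ±20%, ±40%, ±60%, ±80% plus setting the parameter to zero) and the
full strain panel is re-scored.  Bookkeeping is in units of *losses*: a loss
is one perturbation that flipped a phenotype from captured (by that base
vector) to not captured.  Phenotypes a base vector never captured are
excluded from its ledger; perturbations that *gain* a previously missed
phenotype are logged separately and never enter the loss totals.

From the ledger:

* *fragile* phenotypes are those most frequently lost (ranked by share of
  total losses);
* *critical* parameters are those whose perturbation causes the most
  losses; the least critical are *dispensable* and can be zeroed to produce
  a reduced model;
* strongly connected (parameter, phenotype) pairs are individual ledger
  cells with high loss probability;
* zeroing single reaction rates while checking that the wild type stays
  viable screens for synthetic lethality: experimentally viable mutants
  whose call flips to inviable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import StrainModel
from .parameters import ParameterVector, StrainSpec
from .protocol import (
    INVIABLE,
    VIABLE,
    CompiledPanel,
    ProtocolSettings,
    evaluate_objective,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_LEVELS",
    "PerturbationGrid",
    "GridEntry",
    "SensitivityLedger",
    "build_grid",
    "score_grid",
    "rank_fragile",
    "rank_critical",
    "reduce_model",
    "synthetic_lethality_screen",
]

#: eight multiplicative perturbation levels plus the absolute-zero level
DEFAULT_LEVELS: tuple[float, ...] = (0.8, 1.2, 0.6, 1.4, 0.4, 1.6, 0.2, 1.8, 0.0)

#: wildcard base id in an exclusion triple
ANY_BASE = "*"


@dataclass(frozen=True)
class GridEntry:
    base_id: str
    parameter: str
    level: float
    vector: ParameterVector


@dataclass(frozen=True)
class PerturbationGrid:
    """Declarative description of a single-parameter perturbation grid."""

    base_vectors: tuple[tuple[str, ParameterVector], ...]  # (id, vector), ordered
    varying: tuple[str, ...]
    levels: tuple[float, ...] = DEFAULT_LEVELS
    #: (base_id | "*", parameter, level) combos declared non-sensible
    exclusions: frozenset[tuple[str, str, float]] = frozenset()

    def __post_init__(self) -> None:
        if not self.base_vectors:
            raise ValueError("need at least one base vector")
        space = self.base_vectors[0][1].space
        for name in self.varying:
            if name not in space:
                raise ValueError(f"varying parameter {name!r} not in space")

    @property
    def nominal_size(self) -> int:
        """Grid size before exclusions: bases x levels x varying."""
        return len(self.base_vectors) * len(self.levels) * len(self.varying)

    def scheduled_simulations(self, n_strains: int) -> int:
        """Strain simulations implied by the grid before exclusions."""
        return self.nominal_size * n_strains

    def is_excluded(self, base_id: str, parameter: str, level: float) -> bool:
        return (base_id, parameter, level) in self.exclusions or (
            ANY_BASE,
            parameter,
            level,
        ) in self.exclusions


def build_grid(grid: PerturbationGrid) -> Iterator[GridEntry]:
    """Lazily yield every non-excluded perturbed vector.

    Deterministic (base, parameter, level) order; excluded combos are
    silently skipped (callers can compare counts against ``nominal_size``).
    A zero level sets the parameter to 0; other levels multiply it.
    """
    for base_id, base in grid.base_vectors:
        for parameter in grid.varying:
            i = base.space.index(parameter)
            for level in grid.levels:
                if grid.is_excluded(base_id, parameter, level):
                    continue
                values = base.values.copy()
                values[i] = 0.0 if level == 0.0 else values[i] * level
                yield GridEntry(base_id, parameter, level, ParameterVector(base.space, values))


@dataclass
class SensitivityLedger:
    """Loss counts indexed by (parameter, phenotype), plus logged gains.

    Conservation holds exactly: the per-phenotype totals (fragility), the
    per-parameter totals (criticality) and the grand total all sum the same
    loss events.
    """

    loss: dict[tuple[str, str], int] = field(default_factory=dict)
    gains: dict[tuple[str, str], int] = field(default_factory=dict)
    base_bits: dict[str, dict[str, int]] = field(default_factory=dict)
    n_scored: int = 0
    n_skipped: int = 0

    def add_loss(self, parameter: str, phenotype: str) -> None:
        key = (parameter, phenotype)
        self.loss[key] = self.loss.get(key, 0) + 1

    def add_gain(self, parameter: str, phenotype: str) -> None:
        key = (parameter, phenotype)
        self.gains[key] = self.gains.get(key, 0) + 1

    @property
    def total_losses(self) -> int:
        return sum(self.loss.values())

    def fragility(self) -> pd.Series:
        """Loss count per phenotype."""
        out: dict[str, int] = {}
        for (_, phenotype), count in self.loss.items():
            out[phenotype] = out.get(phenotype, 0) + count
        return pd.Series(out, dtype=int).sort_index()

    def criticality(self) -> pd.Series:
        """Loss count per parameter."""
        out: dict[str, int] = {}
        for (parameter, _), count in self.loss.items():
            out[parameter] = out.get(parameter, 0) + count
        return pd.Series(out, dtype=int).sort_index()

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"parameter": p, "phenotype": s, "losses": c}
            for (p, s), c in sorted(self.loss.items())
        ]
        return pd.DataFrame(rows, columns=["parameter", "phenotype", "losses"])


def score_grid(
    grid: PerturbationGrid,
    model: StrainModel,
    protocol: ProtocolSettings,
) -> SensitivityLedger:
    """Re-score every perturbed vector and tally phenotype losses.

    The reference ("captured") set is per base vector.  A perturbed vector
    whose evaluation fails outright counts all of its base's captured
    phenotypes as lost (and is logged).
    """
    panel = CompiledPanel(model)
    ledger = SensitivityLedger()
    for base_id, base in grid.base_vectors:
        ref = evaluate_objective(model, base, protocol, panel=panel)
        ledger.base_bits[base_id] = dict(ref.bits)

    for entry in build_grid(grid):
        ref_bits = ledger.base_bits[entry.base_id]
        captured = [sid for sid, b in ref_bits.items() if b]
        try:
            res = evaluate_objective(model, entry.vector, protocol, panel=panel)
            bits = res.bits
        except Exception:  # noqa: BLE001
            logger.exception(
                "grid evaluation failed (base=%s, parameter=%s, level=%g)",
                entry.base_id, entry.parameter, entry.level,
            )
            bits = None
        if bits is None:
            for sid in captured:
                ledger.add_loss(entry.parameter, sid)
        else:
            for sid, ref_bit in ref_bits.items():
                if ref_bit and not bits[sid]:
                    ledger.add_loss(entry.parameter, sid)
                elif not ref_bit and bits[sid]:
                    ledger.add_gain(entry.parameter, sid)
        ledger.n_scored += 1
    ledger.n_skipped = grid.nominal_size - ledger.n_scored
    return ledger


def _ranked(series: pd.Series, ascending: bool) -> pd.DataFrame:
    df = series.rename("losses").rename_axis("name").reset_index()
    df = df.sort_values(["losses", "name"], ascending=[ascending, True], kind="stable")
    total = int(series.sum())
    df["percent_of_losses"] = (
        np.round(100.0 * df["losses"] / total, 2) if total else 0.0
    )
    return df.reset_index(drop=True)


def rank_fragile(ledger: SensitivityLedger, top_k: Optional[int] = None) -> pd.DataFrame:
    """Phenotypes by descending loss count with percent-of-total-losses."""
    if not ledger.loss:
        raise ValueError("ledger is empty")
    df = _ranked(ledger.fragility(), ascending=False)
    return df if top_k is None else df.head(top_k).reset_index(drop=True)


def rank_critical(
    ledger: SensitivityLedger, bottom_k: int = 0
) -> tuple[pd.DataFrame, list[str]]:
    """Parameters by descending loss count, plus the dispensable bottom-k.

    Parameters that never appear in the ledger (zero recorded losses) are
    not ranked; a caller wanting them dispensable should list them
    explicitly, since the grid may simply not have varied them.
    """
    if not ledger.loss:
        raise ValueError("ledger is empty")
    df = _ranked(ledger.criticality(), ascending=False)
    dispensable = list(df["name"].iloc[len(df) - bottom_k :]) if bottom_k else []
    return df, dispensable


def reduce_model(wt: ParameterVector, dispensable: Iterable[str]) -> ParameterVector:
    """Zero the listed dispensable parameters of a vector (a reduced model)."""
    updates = {}
    for name in dispensable:
        if name not in wt.space:
            raise KeyError(f"unknown parameter {name!r}")
        updates[name] = 0.0
    return wt.with_updates(updates)


def synthetic_lethality_screen(
    model: StrainModel,
    wt: ParameterVector,
    reaction_rates: Sequence[str],
    single_mutants: Optional[Sequence[StrainSpec]] = None,
    protocol: Optional[ProtocolSettings] = None,
) -> pd.DataFrame:
    """Zero one reaction rate at a time and report induced lethality.

    For each rate: the rate is set to 0; if the wild type is no longer
    viable the rate is skipped (flagged in the output).  Otherwise every
    experimentally viable single-mutant strain whose call flips to inviable
    is reported as a (rate, strain) synthetic-lethal pair.
    """
    if protocol is None:
        protocol = ProtocolSettings()
    if single_mutants is None:
        single_mutants = [s for s in model.strains if len(s.transformations) <= 1]
    viable_mutants = [s for s in single_mutants if s.observed == VIABLE]

    base = evaluate_objective(
        model, wt, protocol, panel=CompiledPanel(model, viable_mutants)
    )
    if base.wt_call.call != VIABLE:
        raise ValueError("wild type must be viable at the unperturbed vector")

    panel = CompiledPanel(model, viable_mutants)
    rows = []
    for rate in reaction_rates:
        vec = reduce_model(wt, [rate])
        res = evaluate_objective(model, vec, protocol, panel=panel)
        if res.wt_call.call != VIABLE:
            rows.append(
                {"zeroed_rate": rate, "wt_viable": False, "flipped_strains": ""}
            )
            continue
        flipped = [
            s.strain_id
            for s in viable_mutants
            if res.calls[s.strain_id].call == INVIABLE
        ]
        rows.append(
            {
                "zeroed_rate": rate,
                "wt_viable": True,
                "flipped_strains": ";".join(flipped),
            }
        )
    return pd.DataFrame(rows, columns=["zeroed_rate", "wt_viable", "flipped_strains"])
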