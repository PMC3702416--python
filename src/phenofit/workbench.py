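"""Run configuration, pipeline orchestration and archive serialization.

A run is described by a :class:`RunConfig` (round-trips losslessly to YAML),
executed stage by stage: sample -> filter -> evolve -> compete ->
sensitivity -> reduce, with every stage's tabular output written as plain
CSV and a JSON manifest recording the config, package version and seeds so
a run can be replayed bit-exactly.  A failing stage is recorded in the
manifest; completed stages keep their outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .competition import acceptance_from_archive, competition_profile
from .evolve import DESettings, HIT_PREFIX, run_de
from .parameters import (
    ParameterVector,
    population_from_frame,
    population_to_frame,
    read_params_csv,
    read_strain_csv,
    write_params_csv,
)
from .protocol import ProtocolSettings, evaluate_objective
from .sampling import Hypercube, filter_by_constraint, lh_sample
from .sensitivity import (
    DEFAULT_LEVELS,
    PerturbationGrid,
    rank_critical,
    rank_fragile,
    reduce_model,
    score_grid,
)
from .toymodel import ToyCellCycleModel, make_panel, make_wt

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "summarize", "load_model", "save_archive", "load_archive"]


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    seed: int
    outdir: str
    model: str = "toy"  # built-in toy model, or "module:attribute" plugin path
    params_csv: Optional[str] = None  # center vector; default: model wild type
    strains_csv: Optional[str] = None  # default: model's bundled panel
    # sampling
    fraction: float = 0.4
    n_samples: int = 100
    filter_wt: bool = True
    # evolution
    population: int = 19
    generations: int = 300
    F: float = 0.1
    C: float = 0.5
    selection: str = "non_greedy"
    # protocol
    horizon: float = 2000.0
    dt: float = 0.05
    mass_limit: float = 25.0
    size_tolerance: float = 0.05
    # analyses
    run_evolve: bool = True
    run_compete: bool = True
    run_sensitivity: bool = False
    sensitivity_elites: int = 3
    reduce_bottom_k: int = 0

    def protocol_settings(self) -> ProtocolSettings:
        return ProtocolSettings(
            horizon=self.horizon,
            dt=self.dt,
            mass_limit=self.mass_limit,
            size_tolerance=self.size_tolerance,
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def load_model(spec: str):
    """Resolve a model spec: the built-in ``toy`` or ``module:attribute``."""
    if spec == "toy":
        model, _ = make_wt()
        model.strains = make_panel()
        return model
    modname, _, attr = spec.partition(":")
    if not attr:
        raise ValueError(f"model spec {spec!r} is neither 'toy' nor 'module:attribute'")
    import importlib

    obj = getattr(importlib.import_module(modname), attr)
    return obj() if callable(obj) else obj


def save_archive(archive: pd.DataFrame, path) -> None:
    """Archive CSV plus a sidecar ``.meta.json`` holding the metadata."""
    path = Path(path)
    archive.to_csv(path, index=False)
    meta = {k: v for k, v in archive.attrs.items()}
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


def load_archive(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    if "accepted" in df.columns:
        df["accepted"] = df["accepted"].astype("boolean")
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if meta_path.exists():
        df.attrs.update(json.loads(meta_path.read_text()))
    return df


def summarize(
    archive: pd.DataFrame, convergence_threshold: Optional[int] = None
) -> dict[str, Any]:
    """Digest an archive: best objective per generation, acceptance ratios
    sorted ascending, competitiveness ranking, and the first generation at
    which the population reached a threshold score (if one is given)."""
    if archive.empty:
        return {"generations": 0, "best_by_generation": [], "acceptance_ratio": {},
                "competitiveness": {}, "convergence_generation": None}
    parents = archive[archive["role"] == "parent"]
    best = parents.groupby("generation")["O_sel"].max()
    out: dict[str, Any] = {
        "generations": int(archive["generation"].max()),
        "best_by_generation": [int(v) for v in best],
    }
    acc = acceptance_from_archive(archive, roles=("offspring",)) if (
        (archive["role"] == "offspring").any()
    ) else acceptance_from_archive(archive, roles=("parent",))
    abar = acc.A.mean(axis=0)
    order = np.argsort(abar, kind="stable")
    out["acceptance_ratio"] = {acc.strain_ids[i]: float(abar[i]) for i in order}
    if acc.m >= 2:
        profile = competition_profile(acc)
        rank = profile.ranking()
        out["competitiveness"] = {
            sid: (None if pd.isna(v) else float(v)) for sid, v in rank.items()
        }
    else:
        out["competitiveness"] = {}
    if convergence_threshold is None:
        out["convergence_generation"] = None
    else:
        reached = best[best >= convergence_threshold]
        out["convergence_generation"] = int(reached.index[0]) if len(reached) else None
    return out


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the enabled stages, writing outputs and a replay manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": dataclasses.asdict(config),
        "version": _version,
        "stages": {},
    }
    settings = config.protocol_settings()

    model = load_model(config.model)
    if config.strains_csv:
        model.strains = read_strain_csv(config.strains_csv)
    center = (
        read_params_csv(config.params_csv) if config.params_csv else model.wt_params
    )

    def done(stage: str, **info) -> None:
        manifest["stages"][stage] = {"status": "ok", **info}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    def failed(stage: str, err: Exception) -> None:
        manifest["stages"][stage] = {"status": "failed", "error": repr(err)}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    archive = None
    try:
        cube = Hypercube(center, config.fraction, frozenset(model.fixed_names))
        samples = lh_sample(cube, config.n_samples, seed=config.seed)
        population_to_frame(samples).to_csv(outdir / "samples.csv", index=False)
        if config.filter_wt:
            kept, _ = filter_by_constraint(samples, model, settings)
        else:
            kept = samples
        population_to_frame(kept).to_csv(outdir / "samples_kept.csv", index=False)
        done("sample", n=len(samples), kept=len(kept))
    except Exception as err:  # noqa: BLE001
        failed("sample", err)
        return manifest

    if config.run_evolve:
        try:
            kept_ids = {id(v) for v in kept}
            population = (kept + [s for s in samples if id(s) not in kept_ids])[
                : config.population
            ]
            de = DESettings(
                N=config.population,
                generations=config.generations,
                F=config.F,
                C=config.C,
                selection=config.selection,
                seed=config.seed,
            )
            result = run_de(population, model, de, settings)
            save_archive(result.archive, outdir / "archive.csv")
            result.trace.to_csv(outdir / "trace.csv", index=False)
            archive = result.archive
            done("evolve", best=int(result.trace["best_O_sel"].iloc[-1]))
        except Exception as err:  # noqa: BLE001
            failed("evolve", err)
            return manifest

    if config.run_compete and archive is not None:
        try:
            profile = competition_profile(
                acceptance_from_archive(archive), provenance="de-archive"
            )
            report = {
                "acceptance_ratio": profile.abar.to_dict(),
                "competitiveness": {
                    k: (None if pd.isna(v) else v) for k, v in profile.rhat.items()
                },
                "degenerate": sorted(profile.degenerate),
                "ranking": list(profile.ranking().index),
            }
            (outdir / "competition.json").write_text(json.dumps(report, indent=1))
            done("compete", degenerate=len(profile.degenerate))
        except Exception as err:  # noqa: BLE001
            failed("compete", err)

    if config.run_sensitivity and archive is not None:
        try:
            parents = archive[archive["role"] == "parent"]
            last = parents[parents["generation"] == parents["generation"].max()]
            elite_rows = last.sort_values(
                ["O_sel", "lineage"], ascending=[False, True]
            ).head(config.sensitivity_elites)
            names = archive.attrs["param_names"]
            space = center.space
            varying = tuple(n for n in names if n not in model.fixed_names)
            bases = tuple(
                (f"elite{j}", ParameterVector(space, row[names].to_numpy(dtype=float)))
                for j, (_, row) in enumerate(elite_rows.iterrows())
            )
            grid = PerturbationGrid(bases, varying)
            ledger = score_grid(grid, model, settings)
            ledger.to_frame().to_csv(outdir / "ledger.csv", index=False)
            rank_fragile(ledger).to_csv(outdir / "fragility.csv", index=False)
            crit, dispensable = rank_critical(ledger, config.reduce_bottom_k)
            crit.to_csv(outdir / "criticality.csv", index=False)
            done("sensitivity", total_losses=ledger.total_losses)
            if config.reduce_bottom_k:
                reduced = reduce_model(center, dispensable)
                write_params_csv(reduced, outdir / "reduced_params.csv")
                score = evaluate_objective(model, reduced, settings).objective
                done("reduce", dispensable=dispensable, objective=int(score))
        except Exception as err:  # noqa: BLE001
            failed("sensitivity", err)

    summary = summarize(archive) if archive is not None else {}
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    return manifest
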