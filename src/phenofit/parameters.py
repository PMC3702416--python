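"""Named parameter vectors and strain specifications.

A model's search space is an ordered set of named, nonnegative real
parameters.  Each name carries a role: a kinetic constant of the ODEs or an
initial condition of the state variables.  Mutant strains are expressed as
explicit transformations of the wild-type vector (delete = set to zero,
overexpress = scale, point mutant = set), so the optimizer and all analyses
stay agnostic of any particular model's biology.

Identity is by name, never by position: archives and CSV files carry the
names, and masks of fixed (never-searched) parameters are name sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

KINETIC = "kinetic"
INITIAL_CONDITION = "initial-condition"
_ROLES = (KINETIC, INITIAL_CONDITION)

__all__ = [
    "KINETIC",
    "INITIAL_CONDITION",
    "ParameterSpace",
    "ParameterVector",
    "StrainSpec",
    "Transformation",
    "apply_strain",
    "validate_vector",
    "read_params_csv",
    "write_params_csv",
    "read_strain_csv",
    "write_strain_csv",
]


class UnknownParameterError(KeyError):
    """A transformation or lookup referenced a name absent from the space."""


@dataclass(frozen=True)
class ParameterSpace:
    """Ordered names plus per-name roles, shared by all vectors of a model."""

    names: tuple[str, ...]
    roles: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.roles):
            raise ValueError("names and roles must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("parameter names must be unique")
        for r in self.roles:
            if r not in _ROLES:
                raise ValueError(f"unknown role {r!r}")
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(self.names)})

    @property
    def dimension(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self._index[name]  # type: ignore[attr-defined]
        except KeyError:
            raise UnknownParameterError(name) from None

    def __contains__(self, name: str) -> bool:
        return name in self._index  # type: ignore[attr-defined]

    def kinetic_names(self) -> tuple[str, ...]:
        return tuple(n for n, r in zip(self.names, self.roles) if r == KINETIC)

    def ic_names(self) -> tuple[str, ...]:
        return tuple(n for n, r in zip(self.names, self.roles) if r == INITIAL_CONDITION)


@dataclass(eq=False)
class ParameterVector:
    """A point in parameter space: one value per named parameter.

    ``values`` is a dense float array aligned with ``space.names``; the
    mapping interface is provided for convenience and I/O, the array for the
    hot paths of sampling, evolution and simulation.
    """

    space: ParameterSpace
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.space.dimension,):
            raise ValueError(
                f"expected {self.space.dimension} values, got {self.values.shape}"
            )

    @classmethod
    def from_mapping(
        cls, mapping: Mapping[str, float], roles: Mapping[str, str]
    ) -> "ParameterVector":
        names = tuple(mapping)
        space = ParameterSpace(names, tuple(roles[n] for n in names))
        return cls(space, np.array([mapping[n] for n in names], dtype=float))

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.space.index(name)])

    def __iter__(self) -> Iterator[str]:
        return iter(self.space.names)

    def __len__(self) -> int:
        return self.space.dimension

    def copy(self) -> "ParameterVector":
        return ParameterVector(self.space, self.values.copy())

    def with_updates(self, updates: Mapping[str, float]) -> "ParameterVector":
        out = self.values.copy()
        for name, value in updates.items():
            out[self.space.index(name)] = value
        return ParameterVector(self.space, out)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.space.names), name="value")

    def equals(self, other: "ParameterVector") -> bool:
        return self.space.names == other.space.names and np.array_equal(
            self.values, other.values
        )


#: one parameter change: (target name, op, operand); ops are "set", "scale", "zero"
Transformation = tuple[str, str, float]

_OPS = ("set", "scale", "zero")


@dataclass(frozen=True)
class StrainSpec:
    """One genetic strain: its observed phenotype and how its parameters
    differ from wild type."""

    strain_id: str
    observed: str  # "viable" | "inviable"
    transformations: tuple[Transformation, ...] = ()

    def __post_init__(self) -> None:
        if self.observed not in ("viable", "inviable"):
            raise ValueError(f"observed must be viable/inviable, got {self.observed!r}")
        for name, op, operand in self.transformations:
            if op not in _OPS:
                raise ValueError(f"unknown op {op!r} in strain {self.strain_id}")
            if op != "zero" and not math.isfinite(operand):
                raise ValueError(f"non-finite operand in strain {self.strain_id}")

    def tokens(self) -> str:
        """Serialize transformations to the ``name=expr`` token list."""
        parts = []
        for name, op, operand in self.transformations:
            if op == "zero":
                parts.append(f"{name}=0")
            elif op == "scale":
                parts.append(f"{name}=*{operand:g}")
            else:
                parts.append(f"{name}=={operand:g}")
        return ";".join(parts)

    @classmethod
    def from_tokens(cls, strain_id: str, observed: str, tokens: str) -> "StrainSpec":
        transformations: list[Transformation] = []
        tokens = tokens.strip()
        if tokens:
            for tok in tokens.split(";"):
                name, _, expr = tok.strip().partition("=")
                if not name or not expr:
                    raise ValueError(f"bad transformation token {tok!r}")
                if expr == "0":
                    transformations.append((name, "zero", 0.0))
                elif expr.startswith("*"):
                    transformations.append((name, "scale", float(expr[1:])))
                elif expr.startswith("="):
                    transformations.append((name, "set", float(expr[1:])))
                else:
                    raise ValueError(f"bad transformation expression {expr!r}")
        return cls(strain_id, observed, tuple(transformations))


def apply_strain(wt: ParameterVector, spec: StrainSpec) -> ParameterVector:
    """Turn the wild-type vector into the strain's vector.

    Transformations are applied in listed order: ``set`` overwrites,
    ``scale`` multiplies, ``zero`` sets 0.  The input is never modified.
    Referencing a name absent from the space is a hard error naming the
    offender.
    """
    out = wt.values.copy()
    for name, op, operand in spec.transformations:
        if name not in wt.space:
            raise UnknownParameterError(
                f"strain {spec.strain_id!r} references unknown parameter {name!r}"
            )
        i = wt.space.index(name)
        if op == "zero":
            out[i] = 0.0
        elif op == "scale":
            out[i] *= operand
        else:  # set
            out[i] = operand
    return ParameterVector(wt.space, out)


def compile_transformations(
    space: ParameterSpace, spec: StrainSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pre-resolve a strain's ops to (index, opcode, operand) arrays.

    Opcodes: 0 = set, 1 = scale, 2 = zero.  Used by bulk evaluation so the
    per-vector cost is a few fancy-indexing operations instead of repeated
    name lookups.
    """
    idx, ops, operands = [], [], []
    for name, op, operand in spec.transformations:
        if name not in space:
            raise UnknownParameterError(
                f"strain {spec.strain_id!r} references unknown parameter {name!r}"
            )
        idx.append(space.index(name))
        ops.append(_OPS.index(op))
        operands.append(operand)
    return (
        np.asarray(idx, dtype=np.int64),
        np.asarray(ops, dtype=np.int64),
        np.asarray(operands, dtype=float),
    )


def apply_compiled(values: np.ndarray, idx, ops, operands) -> np.ndarray:
    """Apply pre-compiled transformations to a raw value array (copied)."""
    out = values.copy()
    for k in range(len(idx)):
        i = idx[k]
        if ops[k] == 0:
            out[i] = operands[k]
        elif ops[k] == 1:
            out[i] *= operands[k]
        else:
            out[i] = 0.0
    return out


def validate_vector(v: ParameterVector) -> list[str]:
    """Report invariant violations; an empty list means the vector is valid.

    Never raises: each violation is a human-readable string naming the
    parameter and the broken rule (finiteness or nonnegativity).
    """
    violations: list[str] = []
    for name, value in zip(v.space.names, v.values):
        if not math.isfinite(value):
            violations.append(f"{name}: value {value} is not finite")
        elif value < 0:
            violations.append(f"{name}: value {value} is negative")
    return violations


# ---------------------------------------------------------------------------
# plain-text interchange: two-column CSV with a role column for vectors, and
# a (strain_id, observed, transformations) table for strain panels


def write_params_csv(v: ParameterVector, path) -> None:
    pd.DataFrame(
        {"name": list(v.space.names), "role": list(v.space.roles), "value": v.values}
    ).to_csv(path, index=False)


def read_params_csv(path) -> ParameterVector:
    df = pd.read_csv(path)
    space = ParameterSpace(tuple(df["name"]), tuple(df["role"]))
    return ParameterVector(space, df["value"].to_numpy(dtype=float))


def write_strain_csv(strains: Sequence[StrainSpec], path) -> None:
    pd.DataFrame(
        {
            "strain_id": [s.strain_id for s in strains],
            "observed": [s.observed for s in strains],
            "transformations": [s.tokens() for s in strains],
        }
    ).to_csv(path, index=False)


def read_strain_csv(path) -> list[StrainSpec]:
    df = pd.read_csv(path, keep_default_na=False)
    return [
        StrainSpec.from_tokens(row.strain_id, row.observed, row.transformations)
        for row in df.itertuples()
    ]


def population_to_frame(population: Iterable[ParameterVector]) -> pd.DataFrame:
    population = list(population)
    if not population:
        return pd.DataFrame()
    space = population[0].space
    return pd.DataFrame(
        np.vstack([v.values for v in population]), columns=list(space.names)
    )


def population_from_frame(df: pd.DataFrame, roles: Mapping[str, str]) -> list[ParameterVector]:
    space = ParameterSpace(tuple(df.columns), tuple(roles[c] for c in df.columns))
    return [ParameterVector(space, row) for row in df.to_numpy(dtype=float)]
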