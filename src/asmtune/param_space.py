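"""Mixed-type assembler parameter spaces and their search domains.

A transcript assembler exposes a fixed, ordered list of tunable parameters
(binary flags, integer thresholds, continuous cutoffs).  A :class:`ParamSpace`
records that list; a :class:`ParamVector` is one complete assignment of
native-scale values; a :class:`SearchDomain` is a per-coordinate closed box
used by the optimizer.  Registries for Scallop (18 parameters) and
StringTie2 (8 parameters) are bundled as plain-text TSV files.

Search-domain conventions:

* the initial domain of every non-binary coordinate is ``[0, 10 * default]``;
* binary coordinates always range over ``{0, 1}``;
* after the coordinate-ascent warmup finds an incumbent ``theta_hat``, the
  domain of coordinate ``i`` is widened to ``[0, max(2 * theta_hat[i], U_i)]``
  where ``U_i`` is the initial upper bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ParamSpec",
    "ParamSpace",
    "ParamVector",
    "SearchDomain",
    "load_builtin_space",
    "initial_domain",
    "adjust_domain",
    "validate_vector",
    "BUILTIN_ASSEMBLERS",
]

BUILTIN_ASSEMBLERS = ("scallop", "stringtie2")

_KINDS = ("binary", "integer", "float")


def default_warmup_step(kind: str, default: float) -> float:
    """Native-scale coordinate-ascent step for a parameter.

    Integer parameters step by ``max(1, round(default / 5))``, float
    parameters by ``default / 5`` (floored at 0.1 when the default is at or
    below 0.1), binary parameters are flipped.  The convention is
    configurable per spec via the registry file / ParamSpec field.
    """
    if kind == "binary":
        return 1.0
    if kind == "integer":
        return float(max(1, round(default / 5)))
    step = default / 5.0
    if default <= 0.1 or step <= 0:
        return 0.1
    return step


@dataclass(frozen=True)
class ParamSpec:
    """One tunable parameter: name, kind, native-scale default and step."""

    name: str
    kind: str
    default: float
    warmup_step: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown parameter kind {self.kind!r}")
        if self.kind != "binary" and self.default < 0:
            raise ValueError(f"{self.name}: default must be nonnegative")
        if self.kind == "binary" and self.default not in (0, 1):
            raise ValueError(f"{self.name}: binary default must be 0 or 1")
        if self.warmup_step is None:
            object.__setattr__(
                self, "warmup_step", default_warmup_step(self.kind, self.default)
            )
        if self.kind != "binary" and self.warmup_step <= 0:
            raise ValueError(f"{self.name}: warmup_step must be positive")


@dataclass(frozen=True)
class ParamSpace:
    """Ordered collection of ParamSpecs for one assembler."""

    specs: tuple[ParamSpec, ...]
    assembler_name: str = "custom"

    def __post_init__(self) -> None:
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise ValueError("parameter names must be unique")

    def __len__(self) -> int:
        return len(self.specs)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.specs)

    @property
    def kinds(self) -> tuple[str, ...]:
        return tuple(s.kind for s in self.specs)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def spec(self, name: str) -> ParamSpec:
        return self.specs[self.index(name)]

    def defaults(self) -> "ParamVector":
        return ParamVector(tuple(s.default for s in self.specs))

    def is_binary(self) -> np.ndarray:
        return np.array([s.kind == "binary" for s in self.specs])


@dataclass(frozen=True)
class ParamVector:
    """One point theta in a parameter space, in space order, native scale."""

    values: tuple[float, ...]

    def __init__(self, values: Iterable[float]):
        object.__setattr__(self, "values", tuple(float(v) for v in values))

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, i: int) -> float:
        return self.values[i]

    def __iter__(self):
        return iter(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def replace(self, i: int, value: float) -> "ParamVector":
        vals = list(self.values)
        vals[i] = float(value)
        return ParamVector(vals)


@dataclass(frozen=True)
class SearchDomain:
    """Per-coordinate closed ranges; binary coordinates are fixed to {0,1}."""

    lo: tuple[float, ...]
    hi: tuple[float, ...]
    kinds: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (len(self.lo) == len(self.hi) == len(self.kinds)):
            raise ValueError("lo/hi/kinds length mismatch")
        for l, h in zip(self.lo, self.hi):
            if l < 0 or l > h:
                raise ValueError("domain requires 0 <= lo <= hi")

    def __len__(self) -> int:
        return len(self.lo)

    def lo_array(self) -> np.ndarray:
        return np.asarray(self.lo, dtype=float)

    def hi_array(self) -> np.ndarray:
        return np.asarray(self.hi, dtype=float)

    def clip(self, theta: ParamVector) -> ParamVector:
        """Project a vector onto the box (and the lattice for integer coords)."""
        vals = []
        for v, l, h, k in zip(theta, self.lo, self.hi, self.kinds):
            v = min(max(v, l), h)
            if k in ("integer", "binary"):
                v = float(round(v))
                v = min(max(v, l), h)
            vals.append(v)
        return ParamVector(vals)

    def contains(self, theta: ParamVector) -> bool:
        if len(theta) != len(self):
            raise ValueError("dimension mismatch")
        for v, l, h, k in zip(theta, self.lo, self.hi, self.kinds):
            if not (l <= v <= h):
                return False
            if k in ("integer", "binary") and v != round(v):
                return False
            if k == "binary" and v not in (0.0, 1.0):
                return False
        return True


def _read_registry(text: str, assembler_name: str) -> ParamSpace:
    specs = []
    header: list[str] | None = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            continue
        row = dict(zip(header, fields))
        step = row.get("warmup_step", "")
        specs.append(
            ParamSpec(
                name=row["name"],
                kind=row["kind"],
                default=float(row["default"]),
                warmup_step=float(step) if step else None,
            )
        )
    return ParamSpace(tuple(specs), assembler_name=assembler_name)


def load_builtin_space(assembler_name: str) -> ParamSpace:
    """Load the bundled parameter registry for a supported assembler.

    Supported names: ``scallop`` (Scallop v0.10.2, 18 parameters) and
    ``stringtie2`` (StringTie2 v2.2.1, 8 parameters).
    """
    name = assembler_name.lower()
    if name not in BUILTIN_ASSEMBLERS:
        raise ValueError(
            f"unknown assembler {assembler_name!r}; "
            f"choose one of {BUILTIN_ASSEMBLERS}"
        )
    text = (
        resources.files("asmtune.registries").joinpath(f"{name}.tsv").read_text()
    )
    return _read_registry(text, name)


def initial_domain(space: ParamSpace) -> SearchDomain:
    """[0, 10 * default] per non-binary coordinate; {0, 1} for binary ones."""
    lo, hi = [], []
    for s in space.specs:
        if s.kind == "binary":
            lo.append(0.0)
            hi.append(1.0)
        else:
            lo.append(0.0)
            h = 10.0 * s.default
            if s.kind == "integer":
                h = float(int(round(h)))
            hi.append(h)
    return SearchDomain(tuple(lo), tuple(hi), space.kinds)


def adjust_domain(domain: SearchDomain, theta_hat: ParamVector) -> SearchDomain:
    """Widen each non-binary range to [0, max(2 * theta_hat[i], U_i)].

    ``U_i`` is the upper bound of the supplied (initial) domain; binary
    coordinates are left untouched.
    """
    if len(theta_hat) != len(domain):
        raise ValueError("theta_hat not conformable with domain")
    hi = []
    for v, u, k in zip(theta_hat, domain.hi, domain.kinds):
        if k == "binary":
            hi.append(u)
        else:
            h = max(2.0 * v, u)
            if k == "integer":
                h = float(int(round(h)))
            hi.append(h)
    return SearchDomain(domain.lo, tuple(hi), domain.kinds)


def validate_vector(
    space: ParamSpace, theta: ParamVector, domain: SearchDomain
) -> bool:
    """True iff every coordinate is type-valid and inside the domain."""
    if len(theta) != len(space) or len(theta) != len(domain):
        raise ValueError("dimension mismatch between space, vector and domain")
    for v, spec in zip(theta, space.specs):
        if spec.kind == "binary" and v not in (0.0, 1.0):
            return False
        if spec.kind == "integer" and v != round(v):
            return False
        if not math.isfinite(v):
            return False
    return domain.contains(theta)
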