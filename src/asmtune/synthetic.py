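"""Synthetic fixtures: grouped sample universes, toy GTF cases, canned traces.

The generators here let every stage of the pipeline — optimization,
similarity, encoder training, advising — run end to end with no external
data.  A :func:`make_universe` universe plants the structure the advising
premise relies on: samples in the same group share (up to small jitter) a
planted optimal parameter vector, and their reads are drawn from the same
group reference sequence so their k-mer content is correlated.  Everything
is a pure function of its seed.

The default universe is desk-scale: a 3-coordinate toy parameter space
(integer + float + binary), 4 groups of 6 samples, a 2 kb reference per
group and 100 reads of 100 bp per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assembly_eval import Objective, Transcript, TranscriptSet, synthetic_objective
from .bo import Trace
from .param_space import ParamSpace, ParamSpec, ParamVector, initial_domain

__all__ = [
    "toy_space",
    "SyntheticSample",
    "SyntheticUniverse",
    "make_universe",
    "make_toy_gtf",
    "make_trace",
    "FrozenSurrogate",
]


def toy_space() -> ParamSpace:
    """Small mixed space used by the synthetic universe and examples."""
    return ParamSpace(
        (
            ParamSpec("min_len", "integer", 20.0),
            ParamSpec("weight", "float", 1.0),
            ParamSpec("strict", "binary", 0.0),
        ),
        assembler_name="toy",
    )


@dataclass
class SyntheticSample:
    sample_id: str
    group: int
    reads: list[str]
    objective: Objective
    true_opt: ParamVector


@dataclass
class SyntheticUniverse:
    space: ParamSpace
    group_optima: list[ParamVector]
    samples: list[SyntheticSample]
    seed: int

    def by_group(self, g: int) -> list[SyntheticSample]:
        return [s for s in self.samples if s.group == g]


_BASES = np.array(list("ACGT"))


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    hits = rng.random(len(arr)) < rate
    arr[hits] = _BASES[rng.integers(0, 4, size=int(hits.sum()))]
    return "".join(arr)


_COMP = str.maketrans("ACGT", "TGCA")


def _sample_reads(
    ref: str, n_reads: int, read_len: int, rng: np.random.Generator
) -> list[str]:
    reads = []
    for _ in range(n_reads):
        pos = int(rng.integers(0, max(len(ref) - read_len, 1)))
        read = ref[pos : pos + read_len]
        if rng.random() < 0.5:
            read = read.translate(_COMP)[::-1]
        reads.append(read)
    return reads


def make_universe(
    n_groups: int = 4,
    samples_per_group: int = 6,
    space: ParamSpace | None = None,
    read_params: dict | None = None,
    seed: int = 0,
) -> SyntheticUniverse:
    """Grouped samples with planted optima and group-correlated reads.

    Per group: one planted optimal parameter vector drawn uniformly from
    the space's initial domain (integer coordinates on the lattice), and
    one random reference sequence.  Per sample: a slightly mutated copy of
    the group reference (substitution rate ``mut_rate``), reads drawn from
    it, and a synthetic objective whose global minimum sits at the group
    optimum perturbed by small per-sample jitter on float coordinates.
    """
    if n_groups < 1 or samples_per_group < 1:
        raise ValueError("sizes must be positive")
    space = space or toy_space()
    rp = {"ref_len": 2000, "n_reads": 100, "read_len": 100, "mut_rate": 0.01}
    if read_params:
        rp.update(read_params)
    rng = np.random.default_rng(seed)
    domain = initial_domain(space)
    lo, hi = domain.lo_array(), domain.hi_array()
    binary = space.is_binary()

    group_optima, group_refs = [], []
    for _g in range(n_groups):
        vals = []
        for i, spec in enumerate(space.specs):
            if spec.kind == "binary":
                vals.append(float(rng.integers(0, 2)))
            elif spec.kind == "integer":
                # keep the optimum away from the domain edge so jitter stays legal
                vals.append(float(rng.integers(int(lo[i]) + 1, int(hi[i]))))
            else:
                vals.append(float(rng.uniform(lo[i] + 0.05 * (hi[i] - lo[i]),
                                              hi[i] - 0.05 * (hi[i] - lo[i]))))
        group_optima.append(ParamVector(vals))
        group_refs.append(_random_sequence(rng, rp["ref_len"]))

    samples = []
    for g in range(n_groups):
        for s in range(samples_per_group):
            child = np.random.default_rng((seed, g, s))
            vals = []
            for i, spec in enumerate(space.specs):
                v = group_optima[g][i]
                if spec.kind == "float":
                    v += child.normal(0.0, 0.01 * (hi[i] - lo[i]))
                    v = float(np.clip(v, lo[i], hi[i]))
                vals.append(v)
            opt = ParamVector(vals)
            ref = _mutate(group_refs[g], rp["mut_rate"], child)
            reads = _sample_reads(ref, rp["n_reads"], rp["read_len"], child)
            obj = synthetic_objective(
                opt, space, seed=int(child.integers(0, 2**31 - 1))
            )
            samples.append(
                SyntheticSample(
                    sample_id=f"g{g}s{s}",
                    group=g,
                    reads=reads,
                    objective=obj,
                    true_opt=opt,
                )
            )
    return SyntheticUniverse(space, group_optima, samples, seed)


# ---------------------------------------------------------------------------
# toy GTF cases


def make_toy_gtf(case_name: str) -> tuple[TranscriptSet, TranscriptSet]:
    """Hand-constructed predicted/reference pairs for the evaluation rules."""
    T = Transcript
    if case_name == "perfect":
        refs = [
            T("chr1", "+", ((0, 100), (200, 300))),
            T("chr1", "+", ((500, 600),)),
        ]
        preds = [
            T("chr1", "+", ((0, 100), (200, 300)), abundance=5.0),
            T("chr1", "+", ((500, 600),), abundance=2.0),
        ]
    elif case_name == "shifted_terminal":
        # intron chain identical, terminal exon ends differ
        refs = [T("chr1", "+", ((0, 100), (200, 300)))]
        preds = [T("chr1", "+", ((10, 100), (200, 290)), abundance=1.0)]
    elif case_name == "boundary80":
        # reference length 100; one prediction overlaps exactly 80, one 79
        refs = [
            T("chr1", "+", ((0, 100),)),
            T("chr2", "+", ((0, 100),)),
        ]
        preds = [
            T("chr1", "+", ((0, 80),), abundance=3.0),
            T("chr2", "+", ((0, 79),), abundance=2.0),
        ]
    elif case_name == "tie":
        # equal abundances: transcripts enter/leave the curve together
        refs = [
            T("chr1", "+", ((0, 100), (200, 300))),
            T("chr1", "+", ((400, 500), (600, 700))),
        ]
        preds = [
            T("chr1", "+", ((0, 100), (200, 300)), abundance=2.0),
            T("chr1", "+", ((400, 500), (600, 700)), abundance=2.0),
            T("chr1", "+", ((800, 900), (950, 1000)), abundance=2.0),
        ]
    elif case_name == "mixed":
        # 3 predictions (2 correct), 4 references -> sens 0.5, prec 2/3
        refs = [
            T("chr1", "+", ((0, 100), (200, 300))),
            T("chr1", "+", ((400, 500), (600, 700))),
            T("chr1", "+", ((900, 1000),)),
            T("chr2", "+", ((0, 100), (150, 250))),
        ]
        preds = [
            T("chr1", "+", ((5, 100), (200, 280)), abundance=5.0),
            T("chr1", "+", ((100, 200), (250, 350)), abundance=3.0),
            T("chr1", "+", ((905, 995),), abundance=1.0),
        ]
    else:
        raise ValueError(f"unknown toy GTF case {case_name!r}")
    return (
        TranscriptSet(preds, role="predicted"),
        TranscriptSet(refs, role="reference"),
    )


# ---------------------------------------------------------------------------
# canned traces with frozen surrogates


class FrozenSurrogate:
    """Lookup-table surrogate: posterior mean fixed at given points."""

    def __init__(self, table: dict[tuple, float]):
        self._table = dict(table)

    def posterior_mean(self, theta) -> float:
        key = tuple(theta)
        if key not in self._table:
            raise KeyError(f"frozen surrogate has no value at {key}")
        return self._table[key]


def make_trace(
    mu_values,
    thetas,
    sample_id: str = "fixture",
) -> tuple[Trace, FrozenSurrogate]:
    """A Trace whose surrogate's posterior mean equals mu_values at thetas."""
    mu_values = list(mu_values)
    thetas = [t if isinstance(t, ParamVector) else ParamVector(t) for t in thetas]
    if len(mu_values) != len(thetas):
        raise ValueError("mu_values and thetas must have equal length")
    trace = Trace(sample_id=sample_id)
    for theta, mu in zip(thetas, mu_values):
        trace.append(theta, float(mu))
    surrogate = FrozenSurrogate(
        {tuple(t): float(m) for t, m in zip(thetas, mu_values)}
    )
    return trace, surrogate
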