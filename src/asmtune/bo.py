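"""CAWarm-BO: coordinate-ascent warmup followed by GP Bayesian optimization.

The optimizer minimizes a black-box loss ``f_R(theta)`` over a mixed
binary/integer/float parameter space under a total evaluation budget
(default 200 evaluations, warmup included):

1. *Warmup* starts from the assembler defaults and cycles the coordinates in
   space order, probing one warmup step in each direction (binary: a flip)
   and greedily accepting the better strictly-improving move.  A coordinate
   whose probes both fail has its step halved for the next pass (floored at
   1 for integers); a full pass with no improving move anywhere, or reaching
   the warmup cap (default 60 evaluations), ends the phase.
2. The search domain is then widened around the warmup incumbent
   ``theta_hat`` to ``[0, max(2 * theta_hat[i], U_i)]`` per coordinate.
3. *BO* fits a GP surrogate to all evaluations and repeatedly proposes the
   expected-improvement maximizer (random multistart + local refinement,
   projected onto the integer lattice / binary values) until the budget is
   spent.

An "iteration" always means one objective evaluation; repeated queries of an
already-evaluated vector are served from the objective cache and do not
consume budget.  The returned incumbent is the earliest record attaining the
minimal loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

from .assembly_eval import Objective
from .gp import Surrogate, encode_points, fit_surrogate
from .param_space import (
    ParamSpace,
    ParamVector,
    SearchDomain,
    adjust_domain,
    initial_domain,
)

__all__ = [
    "EvalRecord",
    "Trace",
    "BOConfig",
    "warmup",
    "bo_step",
    "cawarm_bo",
    "expected_improvement",
    "save_trace",
    "load_trace",
]


@dataclass(frozen=True)
class EvalRecord:
    theta: ParamVector
    y: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.y):
            raise ValueError("loss must be finite")


@dataclass
class Trace:
    """Ordered (theta, y) evaluations for one sample."""

    records: list[EvalRecord] = field(default_factory=list)
    sample_id: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def append(self, theta: ParamVector, y: float) -> None:
        self.records.append(EvalRecord(theta, y))

    def best(self) -> EvalRecord:
        """Earliest record attaining the minimal loss."""
        if not self.records:
            raise ValueError("empty trace has no best record")
        ys = [r.y for r in self.records]
        return self.records[int(np.argmin(ys))]

    def thetas(self) -> list[ParamVector]:
        return [r.theta for r in self.records]

    def losses(self) -> np.ndarray:
        return np.asarray([r.y for r in self.records])


@dataclass
class BOConfig:
    max_warmup_evals: int = 60
    total_evals: int = 200
    seed: int = 0
    refit_every: int = 5
    n_candidates: int = 256
    n_refine: int = 3
    gp_alpha: float = 1e-8

    def __post_init__(self) -> None:
        if not (0 < self.max_warmup_evals < self.total_evals):
            raise ValueError("need 0 < max_warmup_evals < total_evals")


class _BudgetedObjective:
    """Wraps an objective: caches within the run, records new evaluations."""

    def __init__(self, objective: Callable, trace: Trace, budget: int):
        self.objective = objective
        self.trace = trace
        self.budget = budget
        self.cache: dict[tuple, float] = {
            tuple(r.theta): r.y for r in trace.records
        }

    @property
    def exhausted(self) -> bool:
        return len(self.trace) >= self.budget

    def __call__(self, theta: ParamVector) -> float:
        key = tuple(theta)
        if key in self.cache:
            return self.cache[key]
        if self.exhausted:
            raise _BudgetExhausted
        y = float(self.objective(theta))
        self.cache[key] = y
        self.trace.append(theta, y)
        return y


class _BudgetExhausted(Exception):
    pass


def _probe_candidates(
    theta: ParamVector, i: int, spec, step: float, domain: SearchDomain
) -> list[ParamVector]:
    """Up/down (or flipped) neighbors of theta along coordinate i, in-domain."""
    if spec.kind == "binary":
        return [theta.replace(i, 1.0 - theta[i])]
    cands = []
    for direction in (+1.0, -1.0):
        v = theta[i] + direction * step
        v = min(max(v, domain.lo[i]), domain.hi[i])
        if spec.kind == "integer":
            v = float(round(v))
        if v != theta[i]:
            cands.append(theta.replace(i, v))
    return cands


def warmup(
    objective: Callable,
    space: ParamSpace,
    domain: SearchDomain,
    config: BOConfig | None = None,
    trace: Trace | None = None,
) -> tuple[ParamVector, Trace]:
    """Coordinate-ascent warmup from the defaults; returns (incumbent, trace)."""
    config = config or BOConfig()
    trace = trace if trace is not None else Trace()
    fn = _BudgetedObjective(objective, trace, config.max_warmup_evals)
    incumbent = domain.clip(space.defaults())
    steps = [s.warmup_step for s in space.specs]
    try:
        y_inc = fn(incumbent)
        while True:
            improved_any = False
            for i, spec in enumerate(space.specs):
                cands = _probe_candidates(incumbent, i, spec, steps[i], domain)
                best_c, best_y = None, y_inc
                for c in cands:
                    y = fn(c)
                    if y < best_y:
                        best_c, best_y = c, y
                if best_c is not None:
                    incumbent, y_inc = best_c, best_y
                    improved_any = True
                elif spec.kind != "binary":
                    # both probes failed: halve the step for the next pass
                    if spec.kind == "integer":
                        steps[i] = max(1.0, round(steps[i] / 2.0))
                    else:
                        steps[i] = max(steps[i] / 2.0, 1e-6)
            if not improved_any:
                break
    except _BudgetExhausted:
        pass
    best = trace.best()
    return best.theta, trace


def expected_improvement(
    mean: np.ndarray, std: np.ndarray, y_best: float
) -> np.ndarray:
    """EI for minimization; zero where the posterior is (near) deterministic."""
    std = np.asarray(std, dtype=float)
    imp = y_best - np.asarray(mean, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(std > 1e-12, imp / std, 0.0)
    ei = np.where(std > 1e-12, imp * norm.cdf(z) + std * norm.pdf(z), 0.0)
    return np.maximum(ei, 0.0)


def _project(x_scaled: np.ndarray, domain: SearchDomain) -> ParamVector:
    lo, hi = domain.lo_array(), domain.hi_array()
    x = lo + np.clip(x_scaled, 0.0, 1.0) * (hi - lo)
    vals = []
    for v, k, l, h in zip(x, domain.kinds, lo, hi):
        if k in ("integer", "binary"):
            v = float(np.clip(round(v), l, h))
        vals.append(float(v))
    return ParamVector(vals)


def bo_step(
    surrogate: Surrogate,
    domain: SearchDomain,
    trace: Trace,
    seed: int | np.random.Generator = 0,
    n_candidates: int = 256,
    n_refine: int = 3,
) -> ParamVector:
    """Propose the next vector: EI maximizer over the (projected) domain."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    d = len(domain)
    y_best = float(trace.best().y)
    lo, hi = domain.lo_array(), domain.hi_array()
    span = np.maximum(hi - lo, 1e-12)

    cand = rng.random((n_candidates, d))
    inc_scaled = (trace.best().theta.as_array() - lo) / span
    local = np.clip(
        inc_scaled + 0.1 * rng.standard_normal((max(n_candidates // 8, 8), d)),
        0.0,
        1.0,
    )
    cand = np.vstack([cand, local])

    def neg_ei(xs: np.ndarray) -> float:
        theta = lo + np.clip(xs, 0, 1) * span
        mean, std = surrogate.posterior(theta[None, :])
        return -float(expected_improvement(mean, std, y_best)[0])

    thetas = lo + cand * span
    mean, std = surrogate.posterior(thetas)
    ei = expected_improvement(mean, std, y_best)
    order = np.argsort(-ei)

    starts = cand[order[:n_refine]]
    refined = [(ei[order[0]], cand[order[0]])]
    for x0 in starts:
        res = minimize(
            neg_ei,
            x0,
            method="L-BFGS-B",
            bounds=[(0.0, 1.0)] * d,
            options={"maxiter": 30},
        )
        refined.append((-res.fun, res.x))

    seen = {tuple(r.theta) for r in trace.records}
    best_proposal, best_val = None, -np.inf
    for val, xs in refined:
        theta = _project(xs, domain)
        if tuple(theta) in seen:
            continue
        if val > best_val:
            best_proposal, best_val = theta, val
    if best_proposal is None:
        # every refined maximizer was already evaluated: fall back to the
        # best unevaluated raw candidate, then to a random lattice point
        for idx in order:
            theta = _project(cand[idx], domain)
            if tuple(theta) not in seen:
                return theta
        return _project(rng.random(d), domain)
    return best_proposal


def cawarm_bo(
    objective: Callable,
    space: ParamSpace,
    config: BOConfig | None = None,
    domain: SearchDomain | None = None,
    sample_id: str = "",
) -> tuple[ParamVector, Trace]:
    """Full run: warmup, domain adjustment, then BO to the total budget."""
    config = config or BOConfig()
    base = domain or initial_domain(space)
    trace = Trace(sample_id=sample_id)
    theta_hat, trace = warmup(objective, space, base, config, trace)
    adjusted = adjust_domain(base, theta_hat)

    rng = np.random.default_rng(config.seed)
    fn = _BudgetedObjective(objective, trace, config.total_evals)
    kernel = None
    step = 0
    while len(trace) < config.total_evals:
        optimize = kernel is None or step % config.refit_every == 0
        surrogate = fit_surrogate(
            trace,
            adjusted,
            optimize=optimize,
            kernel=kernel,
            seed=config.seed,
            alpha=config.gp_alpha,
        )
        kernel = surrogate.gpr.kernel_
        proposal = bo_step(
            surrogate,
            adjusted,
            trace,
            seed=rng,
            n_candidates=config.n_candidates,
            n_refine=config.n_refine,
        )
        n_before = len(trace)
        try:
            fn(proposal)
            if len(trace) == n_before:
                # proposal was a cache hit: spend the iteration on a random
                # unevaluated point instead (tiny lattices may exhaust)
                for _ in range(50):
                    cand = _project(rng.random(len(adjusted)), adjusted)
                    if tuple(cand) not in fn.cache:
                        fn(cand)
                        break
                if len(trace) == n_before:
                    break
        except _BudgetExhausted:  # pragma: no cover - loop guard suffices
            break
        step += 1
    best = trace.best()
    return best.theta, trace


# ---------------------------------------------------------------------------
# Trace persistence (TSV + JSON config sidecar)


def save_trace(
    trace: Trace, path: str | Path, space: ParamSpace, config: BOConfig | None = None
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("sample_id\teval_index\t" + "\t".join(space.names) + "\ty\n")
        for i, rec in enumerate(trace.records):
            vals = "\t".join(f"{v:.17g}" for v in rec.theta)
            fh.write(f"{trace.sample_id}\t{i}\t{vals}\t{rec.y:.17g}\n")
    if config is not None:
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {
                    "max_warmup_evals": config.max_warmup_evals,
                    "total_evals": config.total_evals,
                    "seed": config.seed,
                    "assembler": space.assembler_name,
                },
                indent=2,
            )
        )


def load_trace(path: str | Path) -> Trace:
    trace = Trace()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_params = len(header) - 3
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if not trace.sample_id:
                trace.sample_id = fields[0]
            theta = ParamVector(float(v) for v in fields[2 : 2 + n_params])
            trace.append(theta, float(fields[-1]))
    return trace
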