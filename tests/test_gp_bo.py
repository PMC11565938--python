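import numpy as np
import pytest

from asmtune.assembly_eval import Objective, synthetic_objective
from asmtune.bo import (
    BOConfig,
    Trace,
    bo_step,
    cawarm_bo,
    expected_improvement,
    load_trace,
    save_trace,
    warmup,
)
from asmtune.gp import fit_surrogate
from asmtune.param_space import (
    ParamSpace,
    ParamSpec,
    ParamVector,
    SearchDomain,
    initial_domain,
)


def _trace_from(pairs, sample_id="t"):
    tr = Trace(sample_id=sample_id)
    for theta, y in pairs:
        tr.append(ParamVector(theta), y)
    return tr


# --------------------------------------------------------------------------
# surrogate


def test_surrogate_interpolates_training_points():
    rng = np.random.default_rng(0)
    thetas = rng.uniform(0, 10, size=(12, 2))
    ys = np.sin(thetas[:, 0]) * 0.1 - 0.5 + 0.05 * thetas[:, 1]
    dom = SearchDomain((0.0, 0.0), (10.0, 10.0), ("float", "float"))
    tr = _trace_from(zip(thetas.tolist(), ys.tolist()))
    sur = fit_surrogate(tr, dom)
    mu, _ = sur.posterior(thetas)
    assert np.allclose(mu, ys, rtol=1e-6, atol=1e-6)


def test_surrogate_constant_trace_predicts_constant():
    tr = _trace_from([([0.0], -0.3), ([5.0], -0.3), ([10.0], -0.3)])
    dom = SearchDomain((0.0,), (10.0,), ("float",))
    sur = fit_surrogate(tr, dom)
    mu, _ = sur.posterior(np.array([[2.5], [7.5]]))
    assert np.allclose(mu, -0.3, atol=1e-8)


def test_surrogate_degenerate_trace_rejected():
    tr = _trace_from([([1.0], -0.1), ([1.0], -0.1)])
    dom = SearchDomain((0.0,), (10.0,), ("float",))
    with pytest.raises(ValueError, match="degenerate"):
        fit_surrogate(tr, dom)


def test_posterior_mean_matches_closed_form_fixed_hyperparameters():
    """Two-point GP: mean at the midpoint matches the hand-written formula."""
    from sklearn.gaussian_process.kernels import ConstantKernel, Matern

    dom = SearchDomain((0.0,), (1.0,), ("float",))
    tr = _trace_from([([0.2], -0.8), ([0.8], -0.2)])
    kernel = ConstantKernel(1.0, "fixed") * Matern(
        length_scale=0.5, length_scale_bounds="fixed", nu=2.5
    )
    sur = fit_surrogate(tr, dom, optimize=False, kernel=kernel, alpha=1e-10)

    # independent closed form: mu(x) = k*^T (K + aI)^-1 (y - ybar)*s + ybar
    def matern52(r, ell=0.5):
        a = np.sqrt(5) * r / ell
        return (1 + a + a**2 / 3) * np.exp(-a)

    X = np.array([0.2, 0.8])
    y = np.array([-0.8, -0.2])
    ybar, ystd = y.mean(), y.std()
    yn = (y - ybar) / ystd
    K = matern52(np.abs(X[:, None] - X[None, :])) + 1e-10 * np.eye(2)
    for q in (0.5, 0.35, 0.65):
        kstar = matern52(np.abs(q - X))
        mu_manual = kstar @ np.linalg.solve(K, yn) * ystd + ybar
        assert sur.posterior_mean(ParamVector([q])) == pytest.approx(
            mu_manual, abs=1e-8
        )
    # monotone 1-D slice: midpoint mean lies between the two observations
    mid = sur.posterior_mean(ParamVector([0.5]))
    assert -0.8 < mid < -0.2


# --------------------------------------------------------------------------
# warmup


def test_warmup_constant_objective_stops_after_one_sweep(space3, domain3):
    obj = Objective(lambda th: -0.5)
    theta_hat, trace = warmup(obj, space3, domain3, BOConfig(seed=0))
    # defaults + 2 probes per non-binary coordinate + 1 flip per binary
    n_nonbin = sum(k != "binary" for k in space3.kinds)
    n_bin = sum(k == "binary" for k in space3.kinds)
    assert len(trace) == 1 + 2 * n_nonbin + n_bin
    assert tuple(theta_hat) == tuple(space3.defaults())


def test_warmup_never_stopping_objective_hits_cap():
    """A strictly coordinate-improving objective runs to the 60-eval cap."""
    from asmtune.param_space import load_builtin_space

    space = load_builtin_space("scallop")
    domain = initial_domain(space)
    hi = np.maximum(domain.hi_array(), 1.0)
    obj = Objective(lambda th: -float(np.sum(th.as_array() / hi)) / len(hi))
    _, trace = warmup(obj, space, domain, BOConfig(seed=0))
    assert len(trace) == 60


def test_warmup_finds_separable_grid_argmin(space2int):
    dom = initial_domain(space2int)
    opt = (11.0, 7.0)
    obj = Objective(
        lambda th: float(
            ((th[0] - opt[0]) / 30.0) ** 2 + ((th[1] - opt[1]) / 20.0) ** 2 - 1.0
        )
    )
    theta_hat, trace = warmup(obj, space2int, dom, BOConfig(seed=0))
    # exhaustive-grid argmin of this separable concave-up objective
    grid_best = min(
        (
            (obj(ParamVector([a, b])), (a, b))
            for a in range(int(dom.hi[0]) + 1)
            for b in range(int(dom.hi[1]) + 1)
        )
    )[1]
    assert tuple(theta_hat) == tuple(float(v) for v in grid_best)


def test_warmup_is_deterministic(space3, domain3):
    opt = ParamVector([77.0, 3.3, 1.0])
    obj1 = synthetic_objective(opt, space3, seed=2)
    obj2 = synthetic_objective(opt, space3, seed=2)
    t1 = warmup(obj1, space3, domain3, BOConfig(seed=0))[1]
    t2 = warmup(obj2, space3, domain3, BOConfig(seed=0))[1]
    assert [tuple(r.theta) for r in t1.records] == [
        tuple(r.theta) for r in t2.records
    ]


# --------------------------------------------------------------------------
# acquisition


def test_bo_step_proposal_matches_dense_grid_ei_argmax():
    dom = SearchDomain((0.0,), (1.0,), ("float",))
    tr = _trace_from([([0.15], -0.4), ([0.85], -0.9)])
    sur = fit_surrogate(tr, dom, seed=0)
    grid = np.linspace(0, 1, 2001)[:, None]
    mu, sd = sur.posterior(grid)
    ei = expected_improvement(mu, sd, tr.best().y)
    grid_argmax = grid[int(np.argmax(ei)), 0]
    proposal = bo_step(sur, dom, tr, seed=0, n_candidates=128)
    assert proposal[0] == pytest.approx(grid_argmax, abs=2e-3)


def test_bo_step_stays_in_domain_and_is_deterministic(space3, domain3):
    opt = ParamVector([120.0, 5.0, 0.0])
    obj = synthetic_objective(opt, space3, seed=1)
    _, tr = warmup(obj, space3, domain3, BOConfig(seed=0))
    sur = fit_surrogate(tr, domain3, seed=0)
    p1 = bo_step(sur, domain3, tr, seed=7)
    p2 = bo_step(sur, domain3, tr, seed=7)
    assert tuple(p1) == tuple(p2)
    assert domain3.contains(p1)


# --------------------------------------------------------------------------
# full runs


def test_cawarm_bo_budget_and_monotone_incumbent(space3):
    obj = synthetic_objective(ParamVector([60.0, 2.0, 1.0]), space3, seed=4)
    cfg = BOConfig(max_warmup_evals=15, total_evals=40, seed=0)
    theta_hat, trace = cawarm_bo(obj, space3, cfg)
    assert len(trace) == 40
    best_so_far = np.minimum.accumulate(trace.losses())
    assert np.all(np.diff(best_so_far) <= 0)
    # never worse than the default vector (evaluated first)
    assert trace.best().y <= trace.records[0].y
    assert tuple(theta_hat) == tuple(trace.best().theta)


def test_trace_round_trip(tmp_path, space3):
    obj = synthetic_objective(ParamVector([60.0, 2.0, 1.0]), space3, seed=4)
    cfg = BOConfig(max_warmup_evals=10, total_evals=14, seed=0)
    _, trace = cawarm_bo(obj, space3, cfg, sample_id="s1")
    path = tmp_path / "trace.tsv"
    save_trace(trace, path, space3, cfg)
    again = load_trace(path)
    assert again.sample_id == "s1"
    assert len(again) == len(trace)
    assert np.allclose(again.losses(), trace.losses())
    assert [tuple(r.theta) for r in again.records] == [
        tuple(r.theta) for r in trace.records
    ]
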