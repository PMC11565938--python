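"""BO-informed similarity between representative samples.

Two samples are deemed similar when the parameter vector that is optimal for
one is also nearly optimal for the other.  With a GP posterior mean
``mu_i`` fitted to sample ``i``'s optimization trace, the *normrank* of
sample ``j`` with respect to ``i`` is the fraction of ``i``'s queried
vectors whose posterior mean is strictly below ``mu_i(theta_hat_j)`` — a
rank-based, scale-free measure of how close ``j``'s optimum comes to
``i``'s optimum under ``i``'s own loss surface.  Averaging the two
directions yields a symmetric dissimilarity in [0, 1]; all-pairs
shortest-path reconstruction (Floyd-Warshall over the complete graph)
repairs it into a metric ``D_hat``; the training similarity is
``S_hat = 1 - 2 * D_hat``, in [-1, 1] like a cosine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import floyd_warshall

from .bo import Trace
from .gp import Surrogate, fit_surrogate
from .param_space import ParamVector, SearchDomain

__all__ = [
    "normrank",
    "symmetrize",
    "shortest_path_repair",
    "similarity_from_distance",
    "build_similarity",
    "SimilarityResult",
]


def normrank(
    trace_i: Trace,
    surrogate_i,
    theta_hat_j: ParamVector,
    clip_domain: SearchDomain | None = None,
) -> float:
    """Fraction of trace_i's points with posterior mean strictly below
    the posterior mean at theta_hat_j (ties do not count)."""
    if len(trace_i) == 0:
        raise ValueError("normrank of an empty trace is undefined")
    if clip_domain is not None:
        theta_hat_j = clip_domain.clip(theta_hat_j)
    if hasattr(surrogate_i, "posterior"):
        mu_trace, _ = surrogate_i.posterior(trace_i.thetas())
        mu_j = surrogate_i.posterior_mean(theta_hat_j)
    else:  # frozen lookup-table surrogate from the synthetic module
        mu_trace = np.asarray(
            [surrogate_i.posterior_mean(t) for t in trace_i.thetas()]
        )
        mu_j = surrogate_i.posterior_mean(theta_hat_j)
    return float(np.sum(mu_trace < mu_j)) / len(trace_i)


def symmetrize(nr: np.ndarray) -> np.ndarray:
    """(nr + nr.T) / 2 — the average of the two normrank directions."""
    nr = np.asarray(nr, dtype=float)
    if nr.ndim != 2 or nr.shape[0] != nr.shape[1]:
        raise ValueError("normrank matrix must be square")
    return (nr + nr.T) / 2.0


def shortest_path_repair(d: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths over the complete graph with weights d.

    The output is elementwise <= the input and satisfies the triangle
    inequality; applying the repair twice is a no-op.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    if np.any(np.diag(d) != 0):
        raise ValueError("diagonal must be zero")
    # store every off-diagonal entry explicitly so zero distances count as
    # zero-weight edges (dense zeros would be read as missing edges)
    n = d.shape[0]
    rows, cols = np.where(~np.eye(n, dtype=bool))
    graph = csr_matrix((d[rows, cols], (rows, cols)), shape=(n, n))
    repaired = floyd_warshall(graph, directed=False)
    return np.asarray(repaired)


def similarity_from_distance(dhat: np.ndarray) -> np.ndarray:
    """S_hat = 1 - 2 * D_hat, mapping [0, 1] distances onto [-1, 1]."""
    dhat = np.asarray(dhat, dtype=float)
    if np.any(dhat < 0) or np.any(dhat > 1):
        raise ValueError("repaired distances must lie in [0, 1]")
    return 1.0 - 2.0 * dhat


@dataclass
class SimilarityResult:
    """Final S_hat plus the intermediate matrices for audit."""

    normrank_matrix: np.ndarray
    distance_pre_repair: np.ndarray
    distance_matrix: np.ndarray
    similarity_matrix: np.ndarray
    theta_hats: list[ParamVector]
    surrogates: list


def build_similarity(
    traces: list[Trace],
    domains: list[SearchDomain],
    clip_domains: list[SearchDomain] | None = None,
    surrogates: list | None = None,
    seed: int = 0,
    gp_alpha: float = 1e-8,
) -> SimilarityResult:
    """normrank -> symmetrize -> shortest-path repair -> S_hat pipeline.

    One surrogate per trace is refit on the complete trace (reusing the BO
    GP configuration) unless pre-fitted surrogates are supplied.  Before
    querying sample ``i``'s surrogate at another sample's optimum, the
    optimum is clipped to ``clip_domains[i]`` (defaults to ``domains[i]``)
    to bound GP extrapolation.  The diagonal of the symmetrized distance is
    forced to zero before repair.
    """
    m = len(traces)
    if m == 0:
        raise ValueError("no traces given")
    if len(domains) != m:
        raise ValueError("one domain per trace required")
    clip_domains = clip_domains or domains
    if surrogates is None:
        surrogates = [
            fit_surrogate(tr, dom, seed=seed, alpha=gp_alpha)
            for tr, dom in zip(traces, domains)
        ]
    theta_hats = [tr.best().theta for tr in traces]
    nr = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            nr[i, j] = normrank(
                traces[i], surrogates[i], theta_hats[j], clip_domains[i]
            )
    pre = symmetrize(nr)
    np.fill_diagonal(pre, 0.0)
    dhat = shortest_path_repair(pre)
    shat = similarity_from_distance(dhat)
    return SimilarityResult(
        normrank_matrix=nr,
        distance_pre_repair=pre,
        distance_matrix=dhat,
        similarity_matrix=shat,
        theta_hats=theta_hats,
        surrogates=surrogates,
    )


def save_matrix(matrix: np.ndarray, ids: list[str], path) -> None:
    """Persist a dense matrix as TSV with an id header row/column."""
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(ids) + "\n")
        for sid, row in zip(ids, matrix):
            fh.write(sid + "\t" + "\t".join(f"{v:.8g}" for v in row) + "\n")


def load_matrix(path) -> tuple[np.ndarray, list[str]]:
    with open(path) as fh:
        ids = fh.readline().rstrip("\n").split("\t")[1:]
        rows = [
            [float(v) for v in line.rstrip("\n").split("\t")[1:]] for line in fh
        ]
    return np.asarray(rows), ids
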