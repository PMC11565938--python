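"""Nearest-neighbor parameter advising in the learned embedding space.

A trained index stores, per representative sample, its embedding, the best
parameter vector found by optimization and that vector's loss.  A new
sample is sketched, normalized with the training corpus statistics, encoded
and matched by cosine similarity; the advisor set collects the best
parameter vectors of the ``p`` most similar representatives (most similar
first).  Evaluating the sample's objective on each candidate and taking the
argmin yields the advised parameter vector.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .encoder import SetEncoder
from .param_space import ParamVector
from .sketch import SketchSet, apply_znorm, minhash_sketch

__all__ = [
    "RepresentativeIndex",
    "AdvisorSet",
    "nearest_neighbors",
    "advisor_set",
    "oracle",
]


@dataclass
class RepresentativeIndex:
    ids: list[str]
    embeddings: np.ndarray  # (m, d)
    theta_hats: list[ParamVector]
    best_losses: list[float]

    def __post_init__(self) -> None:
        self.embeddings = np.asarray(self.embeddings, dtype=float)
        m = len(self.ids)
        if not (self.embeddings.shape[0] == len(self.theta_hats) == m):
            raise ValueError("index fields must have one row per sample")

    def __len__(self) -> int:
        return len(self.ids)

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        with open(d / "embeddings.tsv", "w") as fh:
            for sid, z in zip(self.ids, self.embeddings):
                fh.write(sid + "\t" + "\t".join(f"{v:.17g}" for v in z) + "\n")
        with open(d / "theta_hats.tsv", "w") as fh:
            for sid, th, y in zip(self.ids, self.theta_hats, self.best_losses):
                vals = "\t".join(f"{v:.17g}" for v in th)
                fh.write(f"{sid}\t{y:.17g}\t{vals}\n")

    @classmethod
    def load(cls, directory: str | Path) -> "RepresentativeIndex":
        d = Path(directory)
        ids, Z = [], []
        with open(d / "embeddings.tsv") as fh:
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                ids.append(fields[0])
                Z.append([float(v) for v in fields[1:]])
        thetas, losses = [], []
        with open(d / "theta_hats.tsv") as fh:
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                losses.append(float(fields[1]))
                thetas.append(ParamVector(float(v) for v in fields[2:]))
        return cls(ids, np.asarray(Z), thetas, losses)


@dataclass
class AdvisorSet:
    """Candidate parameter vectors, most-similar neighbor first."""

    thetas: list[ParamVector]
    neighbor_ids: list[str]
    similarities: list[float]
    p: int

    def __len__(self) -> int:
        return len(self.thetas)


def nearest_neighbors(
    z_new: np.ndarray, index: RepresentativeIndex, p: int
) -> list[int]:
    """Positions of the p highest-cosine representatives (stable ties)."""
    if p < 1:
        raise ValueError("p must be >= 1")
    if len(index) == 0:
        raise ValueError("empty representative index")
    if p > len(index):
        warnings.warn(
            f"p={p} exceeds index size m={len(index)}; returning all samples",
            stacklevel=2,
        )
        p = len(index)
    z = np.asarray(z_new, dtype=float)
    norms = np.linalg.norm(index.embeddings, axis=1) * np.linalg.norm(z)
    sims = index.embeddings @ z / np.where(norms > 0, norms, 1.0)
    # stable sort on negated similarity keeps index order on exact ties
    order = np.argsort(-sims, kind="stable")
    return [int(i) for i in order[:p]]


def advisor_set(
    sample: Sequence[str] | SketchSet | np.ndarray,
    encoder: SetEncoder,
    index: RepresentativeIndex,
    p: int,
    znorm_stats: dict | None = None,
    sketch_params: dict | None = None,
) -> AdvisorSet:
    """Sketch -> normalize -> encode -> retrieve the p neighbors' optima.

    ``sample`` may be raw reads (sketched with ``sketch_params``), an
    existing :class:`SketchSet` (normalized with ``znorm_stats``), or an
    already-normalized element array.
    """
    if isinstance(sample, np.ndarray):
        x = sample
    else:
        if isinstance(sample, SketchSet):
            sk = sample
        else:
            sk = minhash_sketch(sample, **(sketch_params or {}))
        if znorm_stats is None:
            raise ValueError("znorm_stats required to normalize a sketch")
        x = apply_znorm(sk, znorm_stats)
    z = encoder.encode(x)
    picks = nearest_neighbors(z, index, p)
    norms = np.linalg.norm(index.embeddings, axis=1) * np.linalg.norm(z)
    sims = index.embeddings @ z / np.where(norms > 0, norms, 1.0)
    return AdvisorSet(
        thetas=[index.theta_hats[i] for i in picks],
        neighbor_ids=[index.ids[i] for i in picks],
        similarities=[float(sims[i]) for i in picks],
        p=p,
    )


def oracle(
    advisor: AdvisorSet, objective: Callable[[ParamVector], float]
) -> tuple[ParamVector, float]:
    """Evaluate the objective on every candidate; return the earliest argmin."""
    if len(advisor) == 0:
        raise ValueError("empty advisor set")
    best_theta, best_y = None, np.inf
    failures = []
    for theta in advisor.thetas:
        try:
            y = float(objective(theta))
        except Exception as exc:  # noqa: BLE001
            failures.append(exc)
            continue
        if y < best_y:
            best_theta, best_y = theta, y
    if best_theta is None:
        raise RuntimeError(f"all advisor evaluations failed: {failures}")
    return best_theta, best_y
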