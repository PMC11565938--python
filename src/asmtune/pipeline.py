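"""End-to-end workflows binding the modules together.

TRAIN: per representative sample, run the warm-started Bayesian optimizer
on its objective; drop representatives whose best AUC is below a floor
(default 3e-4, i.e. essentially unassemblable samples); build the
BO-informed similarity matrix; sketch the reads, optionally augment by read
subsampling, z-normalize the corpus, and train the set encoder on the
(extended) similarity labels; finally index the representatives'
embeddings, best parameter vectors and best losses.

ADVISE: sketch a new sample, embed it, retrieve the top-p neighbors' best
parameter vectors, and (given an objective) return the argmin candidate.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .advisor import AdvisorSet, RepresentativeIndex, advisor_set, oracle
from .bo import BOConfig, Trace, cawarm_bo, save_trace
from .encoder import (
    DEFAULT_RATIOS,
    EncoderConfig,
    SetEncoder,
    TrainConfig,
    augment,
    extend_labels,
    train,
)
from .param_space import ParamSpace, ParamVector, adjust_domain, initial_domain
from .similarity import SimilarityResult, build_similarity, save_matrix
from .sketch import SketchSet, apply_znorm, minhash_sketch, znorm_corpus

logger = logging.getLogger("asmtune")

__all__ = ["RunConfig", "TrainedAdvisor", "train_pipeline", "advise"]


@dataclass
class RunConfig:
    """Resolved configuration for one training run (serializable)."""

    assembler: str = "toy"
    bo: BOConfig = field(default_factory=BOConfig)
    sketch_params: dict = field(
        default_factory=lambda: {"k": 21, "s": 1000, "min_count": 2, "seed": 42}
    )
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    p_list: tuple[int, ...] = (1, 5, 30)
    augment_ratios: tuple[float, ...] = DEFAULT_RATIOS
    use_augmentation: bool = True
    min_best_auc: float = 3e-4
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "assembler": self.assembler,
                "bo": vars(self.bo),
                "sketch_params": self.sketch_params,
                "encoder": {
                    "h_layers": list(self.encoder.h_layers),
                    "g_layers": list(self.encoder.g_layers),
                },
                "training": vars(self.training),
                "p_list": list(self.p_list),
                "augment_ratios": list(self.augment_ratios),
                "use_augmentation": self.use_augmentation,
                "min_best_auc": self.min_best_auc,
                "seed": self.seed,
            },
            indent=2,
        )


@dataclass
class TrainedAdvisor:
    """Everything ADVISE needs: encoder, normalization stats, index."""

    encoder: SetEncoder
    znorm_stats: dict
    index: RepresentativeIndex
    similarity: SimilarityResult
    traces: list[Trace]
    loss_history: list[float]
    config: RunConfig

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.encoder.save(d / "encoder.json")
        (d / "znorm.json").write_text(json.dumps(self.znorm_stats))
        self.index.save(d / "index")
        (d / "config.json").write_text(self.config.to_json())
        ids = self.index.ids
        save_matrix(self.similarity.similarity_matrix, ids, d / "similarity.tsv")


def train_pipeline(
    samples: Sequence,
    space: ParamSpace,
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
) -> TrainedAdvisor:
    """Run the TRAIN workflow over representative samples.

    ``samples`` need ``sample_id``, ``reads`` and callable ``objective``
    attributes (the synthetic universe's samples qualify; adapters around
    real assemblers do too).
    """
    config = config or RunConfig()
    t0 = time.time()
    base_domain = initial_domain(space)

    # step 1: per-sample optimization
    traces, theta_hats, kept = [], [], []
    for i, sample in enumerate(samples):
        bo_cfg = BOConfig(**{**vars(config.bo), "seed": config.bo.seed + i})
        theta_hat, trace = cawarm_bo(
            sample.objective, space, bo_cfg, sample_id=sample.sample_id
        )
        best_auc = -trace.best().y
        if best_auc < config.min_best_auc:
            logger.info(
                "dropping %s: best AUC %.2e below floor", sample.sample_id, best_auc
            )
            continue
        traces.append(trace)
        theta_hats.append(theta_hat)
        kept.append(sample)
    if not kept:
        raise RuntimeError("optimization stage retained no representatives")
    logger.info("optimization done: %d samples, %.1fs", len(kept), time.time() - t0)

    # step 2: BO-informed similarity
    domains = [adjust_domain(base_domain, th) for th in theta_hats]
    sim = build_similarity(
        traces,
        domains,
        clip_domains=[base_domain] * len(traces),
        seed=config.seed,
        gp_alpha=config.bo.gp_alpha,
    )
    logger.info("similarity done: %.1fs", time.time() - t0)

    # step 3: sketches, augmentation, contrastive training
    sketches = [
        minhash_sketch(s.reads, sample_id=s.sample_id, **config.sketch_params)
        for s in kept
    ]
    parent_index = list(range(len(kept)))
    all_sketches = list(sketches)
    if config.use_augmentation:
        for i, s in enumerate(kept):
            for aug in augment(
                s.reads, config.augment_ratios, seed=config.seed + i,
                parent_id=s.sample_id,
            ):
                all_sketches.append(
                    minhash_sketch(
                        aug.reads,
                        sample_id=f"{s.sample_id}@{aug.ratio}",
                        **config.sketch_params,
                    )
                )
                parent_index.append(i)
    normalized, stats = znorm_corpus(all_sketches)
    labels = extend_labels(sim.similarity_matrix, parent_index)
    encoder, history = train(
        normalized, labels, config.encoder, config.training
    )
    logger.info("training done: %.1fs", time.time() - t0)

    # index the original representatives (eval-mode embeddings)
    embeddings = np.stack(
        [encoder.encode(normalized[i]) for i in range(len(kept))]
    )
    index = RepresentativeIndex(
        ids=[s.sample_id for s in kept],
        embeddings=embeddings,
        theta_hats=theta_hats,
        best_losses=[tr.best().y for tr in traces],
    )
    trained = TrainedAdvisor(
        encoder=encoder,
        znorm_stats=stats,
        index=index,
        similarity=sim,
        traces=traces,
        loss_history=history,
        config=config,
    )
    if outdir is not None:
        trained.save(outdir)
        for trace in traces:
            save_trace(
                trace, Path(outdir) / f"trace_{trace.sample_id}.tsv", space,
                config.bo,
            )
    return trained


def advise(
    trained: TrainedAdvisor,
    reads_or_sketch,
    p: int,
    objective: Callable[[ParamVector], float] | None = None,
) -> tuple[AdvisorSet, tuple[ParamVector, float] | None]:
    """ADVISE workflow: advisor set plus, optionally, the oracle pick."""
    adv = advisor_set(
        reads_or_sketch,
        trained.encoder,
        trained.index,
        p,
        znorm_stats=trained.znorm_stats,
        sketch_params=trained.config.sketch_params,
    )
    pick = oracle(adv, objective) if objective is not None else None
    return adv, pick


def select_representatives(
    sketches: Sequence[SketchSet], m: int
) -> list[int]:
    """Greedy facility-location selection of m representatives.

    Convenience hook only — canonical training expects an externally
    curated representative list.  Maximizes sum_j max_{i in S} sim(i, j)
    greedily over Mash similarity (1 - distance).
    """
    from .sketch import mash_distance

    n = len(sketches)
    if not (1 <= m <= n):
        raise ValueError("need 1 <= m <= number of sketches")
    sim = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = 1.0 - mash_distance(sketches[i], sketches[j])
    chosen: list[int] = []
    best_cover = np.zeros(n)
    for _ in range(m):
        gains = np.maximum(sim, best_cover[None, :].repeat(n, 0)).sum(axis=1)
        gains[chosen] = -np.inf
        pick = int(np.argmax(gains))
        chosen.append(pick)
        best_cover = np.maximum(best_cover, sim[pick])
    return chosen
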