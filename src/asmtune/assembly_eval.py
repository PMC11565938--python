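"""Transcript-assembly scoring: matching rules, precision/sensitivity, AUC.

The loss optimized throughout the package is the negative area under the
precision-sensitivity curve of a predicted transcript set against a reference
annotation:

* a predicted multi-exon transcript is correct iff its intron chain exactly
  matches a multi-exon reference transcript on the same chromosome/strand
  (terminal exon ends are free);
* a predicted single-exon transcript is correct iff it overlaps a
  single-exon reference transcript by at least 80% of the reference length;
* ranking predictions by expression abundance and sweeping a cutoff over the
  distinct abundances traces the precision-sensitivity curve, whose area
  (trapezoidal, anchored by a rectangle from sensitivity 0 to the first
  point) is the AUC; the loss is ``-AUC``.

Matching is one-to-one: each reference transcript validates at most one
prediction; surplus duplicates count as incorrect.

The module also provides the black-box objectives ``f_R(theta)`` the
optimizer consumes: a synthetic multimodal stand-in with a planted optimum,
and a subprocess adapter around an external assembler binary.
"""

from __future__ import annotations

import shlex
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .param_space import ParamSpace, ParamVector, SearchDomain, initial_domain

__all__ = [
    "Transcript",
    "TranscriptSet",
    "PRPoint",
    "Objective",
    "match_multi_exon",
    "match_single_exon",
    "count_correct",
    "precision_sensitivity",
    "pr_curve",
    "auc",
    "loss",
    "read_gtf",
    "write_gtf",
    "synthetic_objective",
    "external_assembler_objective",
    "MIN_COVERAGE_DEFAULTS",
]

#: assembler default minimum-coverage thresholds (0 is used for evaluation)
MIN_COVERAGE_DEFAULTS = {"scallop": 1.01, "stringtie2": 1.0}


@dataclass(frozen=True)
class Transcript:
    """A transcript as an ordered chain of exon intervals.

    Exons are 0-based half-open ``(start, end)`` intervals, sorted and
    non-overlapping.  ``abundance`` carries the predicted expression level
    (coverage); reference transcripts may leave it at 0.
    """

    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    abundance: float = 0.0
    transcript_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError("transcript needs at least one exon")
        exons = tuple(sorted((int(a), int(b)) for a, b in self.exons))
        for (a, b) in exons:
            if a >= b:
                raise ValueError(f"empty exon interval {(a, b)}")
        for (_, b0), (a1, _) in zip(exons, exons[1:]):
            if a1 < b0:
                raise ValueError("exons overlap")
        object.__setattr__(self, "exons", exons)
        if self.abundance < 0:
            raise ValueError("abundance must be nonnegative")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Ordered intron chain: gaps between consecutive exons."""
        return tuple(
            (e0[1], e1[0]) for e0, e1 in zip(self.exons, self.exons[1:])
        )

    @property
    def length(self) -> int:
        return sum(b - a for a, b in self.exons)


@dataclass
class TranscriptSet:
    """A list of transcripts plus its role (predicted or reference)."""

    transcripts: list[Transcript]
    role: str = "predicted"

    def __post_init__(self) -> None:
        if self.role not in ("predicted", "reference"):
            raise ValueError("role must be 'predicted' or 'reference'")

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts)


@dataclass(frozen=True)
class PRPoint:
    threshold: float
    sensitivity: float
    precision: float


def _strands_compatible(a: str, b: str) -> bool:
    return a == "." or b == "." or a == b


def match_multi_exon(pred: Transcript, refs: TranscriptSet) -> bool:
    """Exact intron-chain match against any multi-exon reference."""
    if pred.n_exons < 2:
        raise ValueError("match_multi_exon requires a multi-exon prediction")
    chain = pred.introns
    for ref in refs:
        if ref.n_exons < 2:
            continue
        if ref.chrom != pred.chrom:
            continue
        if not _strands_compatible(pred.strand, ref.strand):
            continue
        if ref.introns == chain:
            return True
    return False


def match_single_exon(
    pred: Transcript, refs: TranscriptSet, min_overlap: float = 0.8
) -> bool:
    """Overlap with a single-exon reference of >= min_overlap of its length."""
    if pred.n_exons != 1:
        raise ValueError("match_single_exon requires a single-exon prediction")
    (pa, pb) = pred.exons[0]
    for ref in refs:
        if ref.n_exons != 1:
            continue
        if ref.chrom != pred.chrom:
            continue
        if not _strands_compatible(pred.strand, ref.strand):
            continue
        (ra, rb) = ref.exons[0]
        overlap = min(pb, rb) - max(pa, ra)
        if overlap >= min_overlap * (rb - ra):
            return True
    return False


def _match_key_multi(t: Transcript) -> tuple:
    return (t.chrom, t.introns)


def count_correct(
    preds: Sequence[Transcript],
    refs: TranscriptSet,
    min_overlap: float = 0.8,
) -> int:
    """Number of correct predictions under one-to-one reference matching."""
    used = [False] * len(refs.transcripts)
    correct = 0
    for pred in preds:
        for idx, ref in enumerate(refs.transcripts):
            if used[idx] or ref.chrom != pred.chrom:
                continue
            if not _strands_compatible(pred.strand, ref.strand):
                continue
            if pred.n_exons >= 2:
                ok = ref.n_exons >= 2 and ref.introns == pred.introns
            else:
                if ref.n_exons != 1:
                    continue
                (pa, pb), (ra, rb) = pred.exons[0], ref.exons[0]
                ok = min(pb, rb) - max(pa, ra) >= min_overlap * (rb - ra)
            if ok:
                used[idx] = True
                correct += 1
                break
    return correct


def precision_sensitivity(
    preds: TranscriptSet, refs: TranscriptSet, min_overlap: float = 0.8
) -> tuple[float, float]:
    """(sensitivity, precision) = (correct/|refs|, correct/|preds|)."""
    if len(refs) == 0:
        raise ValueError("reference transcript set is empty")
    if len(preds) == 0:
        return 0.0, 0.0
    correct = count_correct(preds.transcripts, refs, min_overlap)
    return correct / len(refs), correct / len(preds)


def pr_curve(
    preds: TranscriptSet,
    refs: TranscriptSet,
    min_coverage: float = 0.0,
    min_overlap: float = 0.8,
) -> list[PRPoint]:
    """Precision-sensitivity points at every distinct abundance cutoff.

    Predictions below ``min_coverage`` are dropped first.  Cutoffs are the
    distinct surviving abundances in descending order; a cutoff keeps every
    transcript with abundance >= cutoff, so equal-abundance transcripts
    enter and leave the curve together.
    """
    if len(refs) == 0:
        raise ValueError("reference transcript set is empty")
    kept = [t for t in preds if t.abundance >= min_coverage]
    if not kept:
        return []
    cutoffs = sorted({t.abundance for t in kept}, reverse=True)
    points = []
    for c in cutoffs:
        sub = [t for t in kept if t.abundance >= c]
        correct = count_correct(sub, refs, min_overlap)
        points.append(
            PRPoint(
                threshold=c,
                sensitivity=correct / len(refs),
                precision=correct / len(sub),
            )
        )
    return points


def auc(
    preds: TranscriptSet,
    refs: TranscriptSet,
    min_coverage: float = 0.0,
    min_overlap: float = 0.8,
) -> float:
    """Area under the abundance-ranked precision-sensitivity curve.

    Points are taken in order of increasing sensitivity (i.e. descending
    cutoff); the area is the rectangle from sensitivity 0 to the first point
    at that point's precision, plus trapezoids between consecutive points.
    """
    points = pr_curve(preds, refs, min_coverage, min_overlap)
    if not points:
        return 0.0
    area = points[0].sensitivity * points[0].precision
    for p0, p1 in zip(points, points[1:]):
        area += (p1.sensitivity - p0.sensitivity) * (
            p1.precision + p0.precision
        ) / 2.0
    return float(area)


def loss(
    preds: TranscriptSet,
    refs: TranscriptSet,
    min_coverage: float = 0.0,
    min_overlap: float = 0.8,
) -> float:
    """Training loss: negative AUC, in [-1, 0]."""
    return -auc(preds, refs, min_coverage, min_overlap)


# ---------------------------------------------------------------------------
# GTF I/O


def read_gtf(path: str | Path, role: str = "predicted") -> TranscriptSet:
    """Read transcripts from a GTF/GFF file (exon features, grouped by id).

    GTF coordinates are 1-based inclusive; they are converted to the
    package's internal 0-based half-open intervals.  Abundance is taken from
    the first of the ``cov``/``coverage``/``FPKM``/``RPKM`` attributes found
    on the transcript or its exons, defaulting to 0.
    """
    from gffutils.feature import feature_from_line

    by_tid: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            feat = feature_from_line(line)
            if feat.featuretype not in ("exon", "transcript"):
                continue
            tid_vals = feat.attributes.get("transcript_id") or feat.attributes.get(
                "ID"
            )
            if not tid_vals:
                raise ValueError(f"feature without transcript_id in {path}")
            tid = tid_vals[0]
            if tid not in by_tid:
                by_tid[tid] = {
                    "chrom": feat.seqid,
                    "strand": feat.strand or ".",
                    "exons": [],
                    "abundance": None,
                }
                order.append(tid)
            rec = by_tid[tid]
            if feat.featuretype == "exon":
                rec["exons"].append((feat.start - 1, feat.end))
            if rec["abundance"] is None:
                for key in ("cov", "coverage", "FPKM", "RPKM"):
                    if key in feat.attributes:
                        rec["abundance"] = float(feat.attributes[key][0])
                        break
    transcripts = []
    for tid in order:
        rec = by_tid[tid]
        if not rec["exons"]:
            continue
        transcripts.append(
            Transcript(
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=tuple(rec["exons"]),
                abundance=rec["abundance"] or 0.0,
                transcript_id=tid,
            )
        )
    return TranscriptSet(transcripts, role=role)


def write_gtf(tset: TranscriptSet, path: str | Path, source: str = "asmtune") -> None:
    """Write a TranscriptSet as GTF (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for i, t in enumerate(tset):
            tid = t.transcript_id or f"T{i + 1}"
            attrs = f'transcript_id "{tid}"; cov "{t.abundance:g}";'
            start = t.exons[0][0] + 1
            end = t.exons[-1][1]
            fh.write(
                f"{t.chrom}\t{source}\ttranscript\t{start}\t{end}\t.\t"
                f"{t.strand}\t.\t{attrs}\n"
            )
            for (a, b) in t.exons:
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{a + 1}\t{b}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Objectives


class Objective:
    """Callable ParamVector -> loss, with a (theta -> y) cache and counter."""

    def __init__(self, fn: Callable[[ParamVector], float], label: str = ""):
        self._fn = fn
        self.label = label
        self.cache: dict[tuple[float, ...], float] = {}
        self.n_evals = 0

    def __call__(self, theta: ParamVector) -> float:
        key = tuple(theta)
        if key in self.cache:
            return self.cache[key]
        y = float(self._fn(theta))
        self.cache[key] = y
        self.n_evals += 1
        return y


def synthetic_objective(
    planted_opt: ParamVector,
    space: ParamSpace,
    shape_params: dict | None = None,
    seed: int = 0,
    domain: SearchDomain | None = None,
) -> Objective:
    """Deterministic multimodal loss with a known global minimizer.

    Each non-binary coordinate contributes a two-scale Gaussian bump around
    the planted optimum (a broad component that guides coarse search plus a
    narrow peak that rewards precise localization), modulated by a shallow
    ripple that introduces local optima away from the planted point; binary
    coordinates contribute 1 when matched and a fixed fraction otherwise.
    The loss is the negated blend of the per-coordinate mean and product
    (the product term couples coordinates), so the range is (-1, 0] with the
    global minimum of exactly -1 attained only at ``planted_opt``.
    """
    shape = {
        "broad_width": 0.35,
        "narrow_width": 0.08,
        "narrow_weight": 0.4,
        "ripple": 0.15,
        "binary_miss": 0.35,
        "interaction": 0.15,
    }
    if shape_params:
        shape.update(shape_params)
    dom = domain or initial_domain(space)
    opt = planted_opt.as_array()
    lo, hi = dom.lo_array(), dom.hi_array()
    scale = np.maximum(hi - lo, 1e-12)
    binary = space.is_binary()
    rng = np.random.default_rng(seed)
    # mild per-coordinate width jitter keeps different samples' landscapes
    # distinct while leaving the argmin untouched
    bw = shape["broad_width"] * rng.uniform(0.85, 1.15, size=len(opt))
    nw = shape["narrow_width"] * rng.uniform(0.85, 1.15, size=len(opt))

    def fn(theta: ParamVector) -> float:
        x = theta.as_array()
        g = np.empty(len(x))
        u = (x - opt) / scale
        broad = (1 - shape["narrow_weight"]) * np.exp(-((u / bw) ** 2))
        narrow = shape["narrow_weight"] * np.exp(-((u / nw) ** 2))
        ripple = 1.0 - shape["ripple"] * np.sin(3 * np.pi * u) ** 2
        g = (broad + narrow) * ripple
        g[binary] = np.where(x[binary] == opt[binary], 1.0, shape["binary_miss"])
        gamma = shape["interaction"]
        return float(-((1 - gamma) * g.mean() + gamma * g.prod()))

    return Objective(fn, label=f"synthetic:{space.assembler_name}")


#: flag templates per assembler; {name} -> CLI flag, binary flags emitted
#: only when set
_FLAG_STYLES = {
    "scallop": lambda name: f"--{name}",
    "stringtie2": lambda name: f"-{name}",
}


def external_assembler_objective(
    sample: str | Path,
    assembler: str,
    annotation: str | Path,
    min_coverage: float = 0.0,
    space: ParamSpace | None = None,
    executable: str | None = None,
    workdir: str | Path | None = None,
) -> Objective:
    """Adapter objective that runs an assembler binary and scores its GTF.

    Each evaluation writes ``theta`` as command-line flags, runs the
    assembler on the aligned sample (SAM/BAM, passed through opaquely),
    parses the emitted GTF and returns ``-AUC`` against the annotation.
    Results are cached per parameter vector.  Failures raise RuntimeError
    carrying the subprocess log.
    """
    from .param_space import load_builtin_space

    space = space or load_builtin_space(assembler)
    flag = _FLAG_STYLES.get(assembler.lower())
    if flag is None:
        raise ValueError(f"no flag mapping for assembler {assembler!r}")
    exe = executable or assembler
    refs = read_gtf(annotation, role="reference")
    wd = Path(workdir) if workdir else Path(tempfile.mkdtemp(prefix="asmtune_"))
    wd.mkdir(parents=True, exist_ok=True)

    def fn(theta: ParamVector) -> float:
        out_gtf = wd / "pred.gtf"
        cmd = [exe]
        for spec, v in zip(space.specs, theta):
            if spec.kind == "binary":
                if v == 1:
                    cmd.append(flag(spec.name))
            else:
                val = int(v) if spec.kind == "integer" else v
                cmd.extend([flag(spec.name), str(val)])
        if assembler.lower() == "scallop":
            cmd.extend(["-i", str(sample), "-o", str(out_gtf)])
        else:
            cmd.extend(["-o", str(out_gtf), str(sample)])
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(
                f"assembler failed ({shlex.join(cmd)}):\n{proc.stderr[-2000:]}"
            )
        try:
            preds = read_gtf(out_gtf, role="predicted")
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"unparsable assembler GTF output: {exc}") from exc
        return loss(preds, refs, min_coverage=min_coverage)

    return Objective(fn, label=f"{assembler}:{Path(str(sample)).name}")
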