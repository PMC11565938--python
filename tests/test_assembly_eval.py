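import itertools

import numpy as np
import pytest

from asmtune.assembly_eval import (
    Transcript,
    TranscriptSet,
    auc,
    loss,
    match_multi_exon,
    match_single_exon,
    precision_sensitivity,
    read_gtf,
    synthetic_objective,
    write_gtf,
)
from asmtune.param_space import ParamVector, initial_domain
from asmtune.synthetic import make_toy_gtf


# --------------------------------------------------------------------------
# independent brute-force oracle: its own matcher and cutoff sweep


def _oracle_correct(preds, refs):
    """One-to-one matching by exhaustive search, written independently."""
    available = list(refs)
    n = 0
    for p in preds:
        for r in available:
            if r.chrom != p.chrom:
                continue
            if "." not in (p.strand, r.strand) and p.strand != r.strand:
                continue
            if len(p.exons) >= 2:
                p_introns = [
                    (p.exons[i][1], p.exons[i + 1][0])
                    for i in range(len(p.exons) - 1)
                ]
                r_introns = [
                    (r.exons[i][1], r.exons[i + 1][0])
                    for i in range(len(r.exons) - 1)
                ]
                hit = len(r.exons) >= 2 and p_introns == r_introns
            else:
                if len(r.exons) != 1:
                    continue
                (a, b), (c, d) = p.exons[0], r.exons[0]
                hit = max(0, min(b, d) - max(a, c)) >= 0.8 * (d - c)
            if hit:
                available.remove(r)
                n += 1
                break
    return n


def _oracle_auc(preds, refs, min_coverage=0.0):
    kept = [t for t in preds if t.abundance >= min_coverage]
    if not kept:
        return 0.0
    pts = []
    for c in sorted({t.abundance for t in kept}, reverse=True):
        sub = [t for t in kept if t.abundance >= c]
        n = _oracle_correct(sub, list(refs))
        pts.append((n / len(refs.transcripts), n / len(sub)))
    area = pts[0][0] * pts[0][1]
    for (s0, p0), (s1, p1) in zip(pts, pts[1:]):
        area += (s1 - s0) * (p1 + p0) / 2
    return area


# --------------------------------------------------------------------------


def test_multi_exon_match_is_intron_chain_only():
    refs = TranscriptSet(
        [Transcript("chr1", "+", ((0, 100), (200, 300)))], role="reference"
    )
    exact = Transcript("chr1", "+", ((0, 100), (200, 300)), abundance=1)
    shifted = Transcript("chr1", "+", ((10, 100), (200, 290)), abundance=1)
    off = Transcript("chr1", "+", ((10, 100), (201, 290)), abundance=1)
    other_strand = Transcript("chr1", "-", ((0, 100), (200, 300)), abundance=1)
    assert match_multi_exon(exact, refs)
    assert match_multi_exon(shifted, refs)  # terminal ends are free
    assert not match_multi_exon(off, refs)
    assert not match_multi_exon(other_strand, refs)


@pytest.mark.parametrize(
    "pred_end,expected", [(100, True), (80, True), (79, False)]
)
def test_single_exon_80_percent_boundary(pred_end, expected):
    refs = TranscriptSet(
        [Transcript("chr1", "+", ((0, 100),))], role="reference"
    )
    pred = Transcript("chr1", "+", ((0, pred_end),), abundance=1)
    assert match_single_exon(pred, refs) is expected


def test_single_exon_boundary_sweep_flips_at_80():
    """Sweeping overlap fractions finds the correctness transition at 80%."""
    refs = TranscriptSet(
        [Transcript("chr1", "+", ((0, 100),))], role="reference"
    )
    outcomes = {}
    for frac100 in range(70, 91):
        pred = Transcript("chr1", "+", ((0, frac100),), abundance=1)
        outcomes[frac100] = match_single_exon(pred, refs)
    first_correct = min(f for f, ok in outcomes.items() if ok)
    assert first_correct == 80
    assert all(ok == (f >= 80) for f, ok in outcomes.items())


def test_precision_sensitivity_hand_counts():
    preds, refs = make_toy_gtf("mixed")
    sens, prec = precision_sensitivity(preds, refs)
    assert sens == pytest.approx(0.5)
    assert prec == pytest.approx(2 / 3)


def test_perfect_assembly_and_empty_predictions():
    preds, refs = make_toy_gtf("perfect")
    assert precision_sensitivity(preds, refs) == (1.0, 1.0)
    assert auc(preds, refs) == pytest.approx(1.0)
    assert loss(preds, refs) == pytest.approx(-1.0)
    empty = TranscriptSet([], role="predicted")
    assert precision_sensitivity(empty, refs) == (0.0, 0.0)
    assert auc(empty, refs) == 0.0
    with pytest.raises(ValueError, match="empty"):
        precision_sensitivity(preds, TranscriptSet([], role="reference"))


def test_duplicate_predictions_count_once():
    refs = TranscriptSet(
        [Transcript("chr1", "+", ((0, 100), (200, 300)))], role="reference"
    )
    t = Transcript("chr1", "+", ((0, 100), (200, 300)), abundance=1)
    preds = TranscriptSet([t, t], role="predicted")
    sens, prec = precision_sensitivity(preds, refs)
    assert (sens, prec) == (1.0, 0.5)


@pytest.mark.parametrize(
    "case", ["perfect", "shifted_terminal", "boundary80", "tie", "mixed"]
)
def test_auc_equals_bruteforce_oracle(case):
    preds, refs = make_toy_gtf(case)
    assert auc(preds, refs) == pytest.approx(_oracle_auc(preds, refs))


def test_auc_three_prediction_example():
    # abundances 5 (correct), 3 (wrong), 1 (correct) against 2 references
    refs = TranscriptSet(
        [
            Transcript("chr1", "+", ((0, 100), (200, 300))),
            Transcript("chr1", "+", ((400, 500), (600, 700))),
        ],
        role="reference",
    )
    preds = TranscriptSet(
        [
            Transcript("chr1", "+", ((0, 100), (200, 300)), abundance=5),
            Transcript("chr1", "+", ((50, 150), (250, 350)), abundance=3),
            Transcript("chr1", "+", ((400, 500), (600, 700)), abundance=1),
        ]
    )
    # cutoffs 5,3,1 -> PR points (0.5,1), (0.5,0.5), (1,2/3)
    expected = 0.5 * 1.0 + 0.0 + 0.5 * (0.5 + 2 / 3) / 2
    assert auc(preds, refs) == pytest.approx(expected)
    assert auc(preds, refs) == pytest.approx(_oracle_auc(preds, refs))
    assert loss(preds, refs) == pytest.approx(-expected)


def test_auc_invariant_to_input_order():
    preds, refs = make_toy_gtf("tie")
    base = auc(preds, refs)
    for perm in itertools.permutations(preds.transcripts):
        assert auc(TranscriptSet(list(perm)), refs) == pytest.approx(base)


def test_min_coverage_monotonically_removes_predictions():
    preds, refs = make_toy_gtf("mixed")
    full = [p.sensitivity for p in __import__("asmtune").assembly_eval.pr_curve(preds, refs, 0.0)]
    prev_final = max(full)
    for mc in (2.0, 4.0, 10.0):
        pts = __import__("asmtune").assembly_eval.pr_curve(preds, refs, mc)
        final = max((p.sensitivity for p in pts), default=0.0)
        assert final <= prev_final
        prev_final = final


def test_gtf_round_trip(tmp_path):
    preds, refs = make_toy_gtf("mixed")
    p = tmp_path / "pred.gtf"
    write_gtf(preds, p)
    again = read_gtf(p, role="predicted")
    assert len(again) == len(preds)
    for a, b in zip(again, preds):
        assert a.exons == b.exons
        assert a.chrom == b.chrom
        assert a.strand == b.strand
        assert a.abundance == pytest.approx(b.abundance)
    assert auc(again, refs) == pytest.approx(auc(preds, refs))


# --------------------------------------------------------------------------
# synthetic objective


def test_synthetic_objective_minimum_and_determinism(space2int):
    dom = initial_domain(space2int)
    opt = ParamVector([17.0, 5.0])
    obj = synthetic_objective(opt, space2int, seed=5)
    assert obj(opt) == pytest.approx(-1.0)
    # exhaustive grid: the planted optimum is the unique argmin
    grid = [
        ParamVector([a, b])
        for a in range(int(dom.hi[0]) + 1)
        for b in range(int(dom.hi[1]) + 1)
    ]
    values = {tuple(t): obj(t) for t in grid}
    best = min(values, key=values.get)
    assert best == tuple(opt)
    assert all(-1.0 <= v <= 0.0 for v in values.values())
    # determinism under re-instantiation with the same seed
    obj2 = synthetic_objective(opt, space2int, seed=5)
    probe = ParamVector([3.0, 11.0])
    assert obj(probe) == obj2(probe)


# --------------------------------------------------------------------------
# external assembler adapter (exercised through a stub executable)


@pytest.fixture
def stub_assembler(tmp_path):
    """A fake 'scallop' that ignores its flags and emits a fixed GTF."""
    from asmtune.assembly_eval import write_gtf
    from asmtune.synthetic import make_toy_gtf

    preds, refs = make_toy_gtf("mixed")
    ref_gtf = tmp_path / "ann.gtf"
    write_gtf(refs, ref_gtf)
    pred_gtf = tmp_path / "canned.gtf"
    write_gtf(preds, pred_gtf)
    exe = tmp_path / "stub_scallop"
    exe.write_text(
        "#!/bin/sh\n"
        'out=""\n'
        'while [ $# -gt 0 ]; do if [ "$1" = "-o" ]; then out="$2"; shift; fi; shift; done\n'
        f'cp {pred_gtf} "$out"\n'
    )
    exe.chmod(0o755)
    return exe, ref_gtf, preds, refs


def test_external_objective_scores_and_caches(tmp_path, stub_assembler):
    from asmtune.assembly_eval import external_assembler_objective
    from asmtune.param_space import load_builtin_space

    exe, ref_gtf, preds, refs = stub_assembler
    space = load_builtin_space("scallop")
    obj = external_assembler_objective(
        sample=tmp_path / "dummy.bam",
        assembler="scallop",
        annotation=ref_gtf,
        executable=str(exe),
        workdir=tmp_path / "work",
    )
    theta = space.defaults()
    y = obj(theta)
    assert y == pytest.approx(loss(preds, refs))
    assert -1.0 <= y <= 0.0
    n = obj.n_evals
    assert obj(theta) == y and obj.n_evals == n  # cached


def test_external_objective_failure_carries_log(tmp_path):
    from asmtune.assembly_eval import external_assembler_objective
    from asmtune.param_space import load_builtin_space

    exe = tmp_path / "broken"
    exe.write_text("#!/bin/sh\necho boom >&2\nexit 3\n")
    exe.chmod(0o755)
    refs_path = tmp_path / "ann.gtf"
    from asmtune.assembly_eval import write_gtf
    from asmtune.synthetic import make_toy_gtf

    write_gtf(make_toy_gtf("perfect")[1], refs_path)
    obj = external_assembler_objective(
        sample=tmp_path / "dummy.bam",
        assembler="scallop",
        annotation=refs_path,
        executable=str(exe),
        workdir=tmp_path / "work",
    )
    with pytest.raises(RuntimeError, match="boom"):
        obj(load_builtin_space("scallop").defaults())
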