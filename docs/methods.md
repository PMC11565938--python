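# Methods

This note documents the models and procedures implemented in asmtune, the
parameter choices that matter, what the synthetic data does and does not
emulate, and the numerical decisions taken where the design was open.

## Problem setting

A transcript assembler 𝒜 maps an aligned RNA-seq sample R and a parameter
vector θ ∈ Θ to a set of transcripts. With a loss ℒ scoring that set
against a reference annotation, f_R(θ) = ℒ(𝒜(R; θ)) is a black-box
function: expensive (one assembler run per evaluation), derivative-free,
and sample-dependent. The package builds a mapping that, for any sample,
proposes a small *advisor set* of parameter vectors whose best member
approaches argmin f_R, without running any optimization on the new sample.

## Assembly loss

The loss is the negative area under the precision-sensitivity curve.
Matching rules: a multi-exon prediction is correct iff its ordered intron
chain is identical to a multi-exon reference transcript on the same
chromosome and strand (terminal exon ends unconstrained); a single-exon
prediction is correct iff it overlaps a single-exon reference by at least
80% of the *reference* length (one-sided, gffcompare-like; the fraction is
configurable). Matching is one-to-one — each reference validates at most
one prediction, so duplicated predictions lower precision. Strand "."
matches either strand. GTF input is 1-based inclusive and converted to
0-based half-open internally.

The curve sweeps a cutoff over the distinct abundances of the (minimum-
coverage-filtered) predictions in descending order; a cutoff keeps all
transcripts with abundance ≥ cutoff, so ties enter and leave together.
The area is integrated in order of increasing sensitivity: a rectangle
from sensitivity 0 to the first point at that point's precision, then
trapezoids between consecutive points. Whether the curve should instead be
anchored at precision 1 is genuinely ambiguous; the rectangle rule is
fixed, documented, and pinned by a brute-force oracle test. Empty
prediction sets score precision 0 and AUC 0. Minimum-coverage defaults are
0 for evaluation, with the assembler-native 1.01 (Scallop) and 1.0
(StringTie2) available.

## Parameter spaces

Bundled registries (plain TSV under `asmtune/registries/`) describe
Scallop v0.10.2 (18 parameters) and StringTie2 v2.2.1 (8 parameters):
name, default, kind ∈ {binary, integer, float}. Binary parameters are
encoded 0/1 (False → 0). The initial search domain is [0, 10 × default]
per non-binary coordinate and {0, 1} for binary ones; integer coordinates
are searched on the integer lattice. Warmup step sizes default to
max(1, default/5) for integers and default/5 for floats (floored at 0.1
when the default is ≤ 0.1); binary coordinates step by flipping. The
exact upstream step schedule is not published, so the convention is a
registry field users can override.

## CAWarm-BO

One "iteration" is one objective evaluation, everywhere; cached repeat
queries are free. Defaults: 60-evaluation warmup cap, 200-evaluation total
budget.

*Warmup* starts at the defaults and cycles coordinates in space order,
probing ± one step per coordinate (binary: flip) and accepting the better
strictly improving move. A coordinate whose two probes both fail has its
step halved for the next pass (integers floored at 1); a complete pass
with no improving move anywhere stops the phase regardless of remaining
step budget — the stop rule takes precedence over halving. Warmup is
deterministic given the configuration.

The search range of coordinate i is then widened to [0, max(2·θ̂[i], U_i)]
around the warmup incumbent θ̂, and GP-based Bayesian optimization runs to
the total budget. The surrogate is a Gaussian process over the unit-box
encoding (min-max scaling by the active domain; binary coordinates as
0/1) with a single ARD Matérn-5/2 kernel — on a 0/1 coordinate the Matérn
value is a fixed monotone function of coordinate agreement, so binary
dimensions act as a categorical-overlap factor without a separate kernel.
Targets are standardized internally; the jitter is 1e-8, increased
tenfold on Cholesky failure. Kernel hyperparameters are re-optimized by
marginal likelihood every 5 BO steps (restart count 1, seeded) and reused
in between; this keeps a 200-evaluation run around 15 s on one core with
no measurable loss in planted-optimum recovery. Acquisition is expected
improvement, maximized by 256 random candidates plus local perturbations
of the incumbent, L-BFGS-B refinement of the top 3, and projection onto
the lattice/binary structure; proposals duplicating an evaluated point
fall back to the best unevaluated candidate. The returned optimum is the
earliest trace record attaining the minimal loss.

This is a generic mixed-space GP optimizer, not a re-implementation of any
specific trust-region BO system; the contracts (budget accounting,
domain feasibility, determinism per seed) are what the rest of the
pipeline relies on.

## BO-informed similarity

For samples i, j with traces 𝒳_i, 𝒳_j and GP posterior means μ_i (refit on
the complete trace with the BO kernel configuration),

    normrank(i, j) = |{(θ_g, y_g) ∈ 𝒳_i : μ_i(θ_g) < μ_i(θ̂_j)}| / |𝒳_i|

with *strict* inequality — exact ties do not count, which also forces
normrank(i, i) = 0 whenever θ̂_i minimizes μ_i over the trace. Before
evaluating μ_i at another sample's optimum, that vector is clipped to
sample i's initial domain to bound GP extrapolation. The matrix is
symmetrized by pairwise averaging, its diagonal forced to zero (GP
smoothing can otherwise leave a small positive self-distance), and
repaired into a metric by all-pairs shortest paths over the complete graph
(Floyd–Warshall; zero-weight edges are kept as real edges). The repair
only shrinks entries, is idempotent, and restores the triangle
inequality. The training similarity is Ŝ = 1 − 2·D̂ ∈ [−1, 1], matching
the range of a cosine. Dense Floyd–Warshall is O(m³) and comfortable to
m ≈ 10³ representatives.

## Sketch representation

Reads are decomposed into canonical k-mers (lexicographic minimum of the
k-mer and its reverse complement; windows containing non-ACGT symbols are
skipped), k-mers with count < 2 are discarded as likely errors, each
survivor is hashed, and the s smallest distinct hash values are kept with
their counts (k = 21, s = 1000 defaults). The hash packs the canonical
k-mer into 2 bits/base — numeric order of the packing equals lexicographic
order — and applies a seeded splitmix64-style 64-bit finalizer; the only
contract is a fixed deterministic seed-configurable hash. The Mash
distance −ln(2j/(1+j))/k uses the bottom-s Jaccard estimate over the
sketch union and saturates at 1 when no hashes are shared.

Both element dimensions (hash value, count) are z-score normalized with
statistics pooled over the *training corpus*, not per sample: per-sample
normalization would destroy cross-sample comparability of hash values.
The stored statistics are applied unchanged to new samples.

## Set encoder and contrastive training

The encoder is a DeepSets composition Enc(X) = g(mean_i h(x_i)) with
fully connected subnets h: (2, 128, 128, 128, 128) and
g: (128, 256, 256, 256, 64); every layer except the last of each subnet is
followed by batch normalization then ReLU. Mean pooling gives permutation
invariance; at inference batch normalization uses running statistics and
the elements are sorted canonically before pooling, so the embedding is
deterministic and *bit-identical* under input permutation. During
training, batch-norm statistics are pooled over all elements of the
minibatch (standard BatchNorm); per-set statistics were considered and
rejected as they make train-time behavior depend on set boundaries
without affecting the inference-mode contract.

The loss is the cosine mean-squared error
(1/N²)·Σ_ij (cos(z_i, z_j) − Ŝ_ij)², including the i = j terms (which are
exactly zero when the diagonal labels are 1); no temperature or other
extra hyperparameter exists. Optimization is Adam (lr 1e-3, batch 128,
400 epochs by default) with batches drawn without replacement per epoch;
a zero-norm embedding raises rather than being silently regularized. The
network, backpropagation and optimizer are implemented directly on numpy
arrays; gradient correctness is pinned by a finite-difference test.

Data augmentation subsamples each representative's reads per-read
Bernoulli at ratios 0.65, 0.7, 0.75, 0.8, 0.85, 0.9, 0.95 — seven
variants, expanding the training set eight-fold with zero additional
objective evaluations. Cross-parent pairs inherit the parents' Ŝ entry;
pairs within one family (parent with its subsample, or two subsamples of
the same parent) get label 1, a choice the cross-parent rule does not
cover but which encodes the premise that a subsample proxies the same
objective. Batches are uniform over all items; no family stratification.

## Advising

Representative embeddings are precomputed and cached in the index
(re-encoding them per query would change nothing and cost more). A query
is sketched, normalized, embedded, and matched by exact cosine scan
(m ~ 10³; no approximate NN needed). Ties break by stable index order;
p > m returns all m with a warning. The advisor set keeps duplicates —
distinct neighbors may share θ̂. Exposed set sizes default to
p ∈ {1, 5, 30}. Given an objective, the oracle evaluates every candidate
and returns the earliest argmin, so the oracle loss is monotone
non-increasing in p.

Representative-sample *selection* is a hook accepting an external id
list; the trainer also applies a configurable floor (default best AUC
≥ 3e-4) that drops representatives whose objective is essentially flat
at zero.

## Synthetic data: what it emulates and what it does not

`make_universe` plants the structure the advising premise needs: groups of
samples share (up to small float-coordinate jitter) a planted optimal
parameter vector, and reads within a group are drawn from one random
reference sequence (per-sample 1% substitutions), so k-mer similarity is
coupled to objective similarity. The synthetic objective is separable up
to a small product interaction: per non-binary coordinate, a broad plus a
narrow Gaussian bump around the optimum modulated by a shallow ripple
(local optima away from the optimum); binary coordinates score 1 when
matched, 0.35 otherwise. Its range is (−1, 0] and its unique global
minimizer is the planted optimum — verified by exhaustive grid on small
spaces.

Desk-scale defaults: 4 groups × 6 samples, 3-coordinate toy space
(integer, float, binary), 2 kb group references, 100 reads × 100 bp per
sample. These sizes keep full-pipeline runs to minutes on one core and
are stated here as the package's own test conditions.

What passing tests therefore show: the optimizer recovers planted optima
within budget; the similarity pipeline recovers planted group structure
and anticorrelates with cross-evaluated objective values; augmentation
measurably improves held-out label correlation; end-to-end advising beats
the defaults on held-out samples of planted groups. What they do not
show: performance on real RNA-seq read distributions (no error model, no
isoform structure, no coverage unevenness), real assembler loss surfaces,
or corpus sizes near 10³ representatives. One behavior observed on the
synthetic universe carries a practical warning: within-group similarity
labels below 1 (noise from finite optimization budgets and per-sample
jitter) force the encoder to separate nearly identical sketches, which
makes held-out retrieval seed-sensitive on this deliberately degenerate
geometry — real corpora, whose sketch space is not partitioned into
hash-disjoint islands, give the encoder smoother structure to
interpolate.

## Numerical choices and degenerate inputs

- Loss values must be finite; a degenerate trace (all θ identical) cannot
  be fit and raises.
- GP interpolation is noise-free up to jitter 1e-8; surrogate tests check
  recovery of training targets to 1e-6 relative.
- Ties in the incumbent break to the earliest record; cosine ties in
  retrieval break to index order.
- Empty read sets sketch to empty sets and cannot be encoded (error);
  a zero-variance normalization dimension raises.
- Persistence formats are plain text (TSV traces and matrices, JSON
  sketches/weights/config) with floats at 17 significant digits so
  round-trips are exact.

## Known limitations

- The external-assembler adapter shells out with a simple flag mapping
  per assembler and reads abundance from cov/coverage/FPKM attributes; it
  is exercised in tests only through a stub executable.
- The warmup step schedule and the PR-curve anchoring rule are fixed
  documented conventions where upstream practice is unpublished.
- No GPU path; the numpy encoder is desk-scale (hundreds to a few
  thousand training items).
- Representative selection (facility-location submodular selection over a
  large corpus) is out of scope; the hook accepts an external list.
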