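# Methods

This note records the models, parameter choices and numerical
conventions behind `lncnet`, and what the synthetic validation does and
does not demonstrate.

## Synthetic data model

The generator emulates a bulk expression time course of regenerating
liver: 4 stages (days 0, 1, 7, 14), `replicates_per_stage = 3` (a
typical array-study group size; the generator accepts any value ≥ 2),
and a probe mixture of 800 lncRNAs and 1200 mRNAs by default. A gene
`g` planted in module `m` with membership strength `u_g` is generated on
the log2 scale as

    x_{g,i} = b_g + u_g · e_m(stage(i)) + sqrt(1 − u_g²) · ε_{g,i}

with baseline `b_g ~ N(8, 1.5)` (normalized-intensity scale), noise
`ε ~ N(0, noise_sd)` and `e_m` a standardized per-stage trajectory.
`noise_sd` defaults to 1 so that trajectory and noise have equal
variance; `u_g` is then exactly the expected correlation between the
gene and its module trajectory, and `u_g·u_h` the expected intra-module
gene–gene correlation. Membership strengths are uniform on
`membership_range` (default 0.7–0.95). Background genes (85% of probes
by default) are baseline plus noise. Defaults plant 5 modules of 60
genes in a 2000-probe design — a deliberate ~5× scale-down of an
11 000-probe differential universe, sized so the full pipeline and the
multi-seed recovery studies run in seconds on one CPU.

**Trajectory bank.** An unsigned network (|r|^β) cannot distinguish a
module from its mirror image: two monotone trajectories of opposite
sign correlate near −1, and the corresponding modules would merge. The
4-stage bank therefore holds five standardized profiles numerically
optimized to minimize the maximum pairwise |Pearson r| subject to
keeping one strongly day-positive (late rise, r = +0.84 with the day
vector) and one strongly day-negative (early activation then decline,
r = −0.84) profile. The optimum reaches max |r| = 0.454, essentially
the equiangular-lines bound 1/√5 for five directions in the
3-dimensional centered stage space — both signs of module–stage
correlation occur, yet every pair of modules stays separable. For stage
counts other than 4 a standardized discrete-cosine basis is used.
Biotypes are interleaved within modules so both lncRNAs and mRNAs can
pass the downstream GS/MM filters.

**What the generator does not model:** probe-level replicates, spatial
array artifacts, missing values, heteroscedastic or heavy-tailed noise,
correlated background structure (batch effects), or modules with
internal sub-structure. Passing the recovery suites therefore shows the
pipeline is correct and well-calibrated under a clean additive model —
not that it is robust to the pathologies of real arrays.

## Differential expression

Per comparison (baseline day vs test day) each probeset gets a
two-sided Student pooled-variance t-test on log2 intensities and an
absolute fold change `2^|Δmean log2|`; it passes when p < 0.05 and
FC > 2, both strict. Student rather than Welch is used inside the
pipeline: at 3 vs 3 the Welch–Satterthwaite approximation has true size
≈ 0.035 at nominal 0.05 (measured by simulation), which would make the
null calibration check fail by construction, whereas the pooled test is
exact under the generator's equal-variance noise. A `welch_t` routine
with the usual conventions (both groups constant and equal → (0, 1);
constant with different means → (±inf, 0)) is provided for
unequal-variance use. P-values are deliberately unadjusted within a
comparison; selection is a per-gene screen, not an inference. Passing
probesets are united across comparisons and collapsed to symbols,
keeping per symbol the probe with the largest |log2 FC| over all
comparisons (ties by probe id).

## Network construction

Correlations are exact Pearson across samples (≥ 3 samples required;
zero-variance genes are an error, not silently dropped). Adjacency is
unsigned, `a = |r|^β`. The scale-free fit bins connectivities into 10
equal-width bins and regresses log10(frequency) on log10(mean k); the
reported statistic is −sign(slope)·R², so heavy-tailed distributions
score near +1 and a degenerate all-equal-k network scores 0 with a
warning. β is the smallest power in 1..30 reaching signed R² ≥ 0.85,
else the argmax; a user override (e.g. 18) bypasses selection but the
fit table is still reported. The TOM uses the canonical unsigned
formula with the min-connectivity denominator; the implementation is a
single matrix product and is checked against a triple-loop oracle.

## Hybrid tree cut

Average-linkage (UPGMA, via scipy) on `1 − TOM` gives the dendrogram.
The cut proceeds in four deterministic stages:

1. **Branches.** Static cut at `cut_height`, default
   `max(median merge height, 0.5 × max merge height)`. The default is
   rank-based on purpose: raising β compresses all TOM values toward 0
   (dissimilarities toward 1), so no fixed absolute height works across
   powers, while the merge *order* is unaffected. The 0.5·max floor
   keeps noiseless block-structured inputs from being cut inside their
   blocks. Branches with ≥ `min_module_size // 2` (min 3) leaves are
   candidates.
2. **Cohesion filter.** A candidate survives only if its mean internal
   similarity (1 − dissimilarity) is ≥ 2× its mean similarity to
   non-members. Genuine modules exceed this by an order of magnitude at
   any β; agglomerations of noise sit near ratio 1, so an all-noise
   network yields zero modules. The factor 2 has a wide valid window
   (roughly 1.5–10 in pilot simulations) and is not sensitive.
3. **Trim.** Each surviving branch is trimmed to the members whose
   average dissimilarity to the branch lies in its lowest 55% — genes
   with chance correlation to the module trajectory attach to real
   branches just below any workable cut height, and this removes them.
4. **Grow.** Every gene (including trimmed ones) joins its nearest core
   if its average dissimilarity to the core is within the core radius
   (0.95-quantile of the core members' own within-core averages); else
   it is unassigned. Modules under `min_module_size` are dissolved and
   labels are renumbered M1..Mk by decreasing size. `unassigned` is
   never counted as a module.

The trim/grow quantiles were fixed by pilot simulation on one batch of
generator seeds and validated on a held-out batch (20/20 seeds with
adjusted Rand index ≥ 0.9) before the test suite was frozen. On
noiseless block dissimilarities stages 2–4 are no-ops and the cut
reduces to the plain static branch cut. This is a defined,
deterministic simplification of the published dynamic hybrid algorithm
— there is no recursive deep-split — so nested module structures that
only a deep split would separate are out of scope.

`min_module_size` defaults to 30 in the library. The pipeline runs the
network on the DE-filtered symbol matrix (~400 genes at the default
study size), where detected planted modules settle around 20–35 genes;
its config therefore defaults to 20, the same default as the reference
blockwise implementation. Both are exposed on the CLI.

Eigengenes are the first right singular vectors of row-standardized
module submatrices, sign-oriented to correlate non-negatively with the
module mean profile; variance explained is the first squared singular
value over the total. No eigengene-based module merging is performed by
default.

## Module–stage scores and the hub funnel

The primary trait encoding is the numeric day vector, which yields one
signed correlation per module; 0/1 stage indicators are also emitted
for heatmap-style tables. Correlation p-values are two-sided Student t
with n − 2 df; r = ±1 maps to p = 0. GS and MM are absolute
correlations (thresholds act on magnitude); signed values are stored
alongside. The key module maximizes |r| against the primary trait, ties
broken by size then label.

The funnel applies strict GS > 0.5 and MM > 0.9, restricts the supplied
interaction graph to the key mRNAs, ranks by unnormalized shortest-path
betweenness (equal splitting over tied shortest paths; isolated nodes
count 0), and keeps the top 20 mRNAs (ties lexicographic) and the 10
key lncRNAs with smallest GS p (ties lexicographic). The co-expression
network tests all mRNA–mRNA and lncRNA–mRNA pairs among the survivors;
an edge needs |r| ≥ 0.9 (inclusive) *and* p < 0.05. The |r| ≥ 0.9
default matches the MM > 0.9 stringency; there is no published numeric
threshold for this step, and both thresholds are exposed. Hub genes are
the ranked key genes with at least one edge. Fewer-than-k candidate
pools produce warnings, never errors, and all tie-breaks are fully
specified so identical inputs give byte-identical hub lists.

## Enrichment

Hypergeometric upper tail P(X ≥ overlap) on sets intersected with the
universe; rows with overlap < 5 are dropped before Benjamini–Hochberg
adjustment (the ≥ 5-gene display convention). Per-collection
significance conventions (FDR-based vs raw-p-based) are left to the
caller; the table reports both columns.

## Pipeline

`run_pipeline` executes simulate/load → DE → network → module–stage →
hubs → enrichment, writes every intermediate as TSV (expression floats
with `%.17g`, so write→read round-trips bit-exactly), a parameter
sidecar and a JSON report. Identical config and seed give byte-identical
outputs; the one global seed fans out to independent component streams
(expression, interaction graph, gene sets) via seed sequences. In
file-input mode a missing interaction graph downgrades the betweenness
step (all key mRNAs proceed, with a warning); an empty differential
universe or zero detected modules abort with a stage-named error.

## Known limitations

- Module recovery degrades gracefully but detectably after the DE
  filter at high β: weakly planted members are statistically
  indistinguishable from background at 12 samples, so detected modules
  are pure but smaller than planted (the cohesive core), and a planted
  module can fall under the size floor in some seeds.
- Membership recovery is sampling-limited: with 12 samples the
  within-module Spearman between planted strength u and measured MM
  plateaus near 0.78 (the sd of a sample correlation at n = 12 is
  comparable to the spread of u itself). This is a property of the
  design size, not of the estimator.
- No block-wise processing: matrices are dense, so > 20 000 genes is out
  of intended scope; no signed or signed-hybrid networks; no biweight
  midcorrelation; no moderated-variance differential testing.
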