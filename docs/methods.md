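# Methods

This note documents the models implemented in `epicdrem`, the assumptions
behind them, the defaults that matter, and what the synthetic fixtures do
and do not establish about real data.

## Coordinate and format conventions

All coordinates are 0-based half-open (BED convention). One-based TSS
tables are shifted on read. bedGraph tracks are step functions; overlapping
bedGraph intervals are rejected rather than summed, because a coverage
track that overlaps itself is ambiguous. JASPAR motif blocks are parsed
with Biopython; MEME letter-probability blocks are parsed in-package
(the strict "minimal MEME" reader requires a background-frequency line
that many MEME files omit). Count matrices are regularized with a
pseudocount (default 0.01 per cell) before renormalization so that
log-ratio energies remain finite; the default is small enough to leave
informative columns essentially unchanged.

## Biophysical affinity model

A region's affinity for a TF is the expected number of bound TF molecules
under an independent-site occupancy model: each motif-length window on
either strand contributes `R0·e^(−E/λ)/(1 + R0·e^(−E/λ))`, where E is the
sum over columns of `ln(p_max/p_base)`. There is no hard hit threshold —
many weak sites can accumulate as much occupancy as one strong site, which
is the property that distinguishes this score from hit counting.

Parameters: λ = 0.7 and ln R0 = 0.584·L − 5.66 (L = motif length), the
published defaults of the occupancy model this score follows; both are
exposed in `TrapParameters`. Windows containing N score exactly 0 (no
renormalization over fewer windows, which would overstate the affinity of
gappy sequence). Affinities are normalized by each region's own length to
a per-bp scale; region sets of heterogeneous width are otherwise not
comparable. (The source describing this normalization divides, in its
printed formula, the footprint affinity by the *random region's* length —
an evident typographical slip; each affinity is divided by its own
region's length here.)

## Empirical background and binarization

Affinities carry no universal scale, so the bound/unbound cutoff is
empirical. For each footprint, 10 random regions (configurable) of
identical length are sampled uniformly from N-free genome positions and
accepted when their GC content is within ±0.05 of the footprint's; after
1,000 rejected draws the GC bin doubles, with a logged warning, so
degenerate genomes cannot stall the sampler. Background regions never
overlap footprints — the null should not contain signal. Backgrounds are
shared across TFs within a time point (the background depends only on the
regions, not the motif), and every time point gets its own background
because its footprint set differs.

The per-TF threshold at P-value p (default 0.05) is the smallest affinity
present in the background whose strict exceedance fraction is ≤ p;
binarization is strict (`a′ > t`, equality → 0). With a continuous
affinity distribution and n background values, exactly ⌊pn⌋ background
regions exceed the threshold, which is the calibration property the
acceptance script measures (0.05 at n = 10,000).

## TF–gene association

The association window is tss ± 50 kb around the gene's 5′-most TSS
(minimum coordinate on +, maximum on −), clipped at the chromosome start;
any ≥ 1 bp overlap between the closed window and a binarized-positive
footprint sets a_gi = 1. Association is monotone in the window half-width
by construction. The promoter baseline scores a 2 kb window centered on
the TSS directly from sequence with the same thresholding scheme — it
represents annotation-only approaches with no chromatin time-dependence.
The shuffle control permutes the tf, gene and time columns of the
long-form association records independently, preserving every marginal
count while destroying the mapping.

## Temporal path model

The original dynamic-regulatory-map machinery is an input–output hidden
Markov model; this package deliberately implements a smaller model with
the same tree semantics, because all downstream statistics consume only
the tree. At each time point t > 0, the per-gene change
`x[:, t] − x[:, t−1]` is clustered by seeded 1-D k-means (k = `n_states`,
10 restarts); cluster centers closer than `min_state_separation` (default
1.0 log2 unit) are merged, so a state marks a genuinely distinct
expression change rather than a noise quantile. Within each current path,
genes partition by state; children smaller than `min_path_genes` (default
20) are absorbed into their largest sibling, and a node with ≥ 2 surviving
children is a split. Children therefore always partition their parent and
every gene follows exactly one root-to-leaf path. Exact tie-breaking for
genes equidistant between states is whatever seeded k-means assigns; runs
are reproducible for a fixed seed.

## Split scores, aggregation, ranking

At a split with gene population N (K of them targets of TF i), each
emanating path of size n with k targets gets the one-sided hypergeometric
tail p = P(X ≥ k). Bonferroni correction multiplies by the number of TFs
scored at the split; the *split score* is −log2 of the corrected value.
Per TF and time point, Fisher's method aggregates over the splits at that
time point: X = −2 Σ ln p (natural log, as Fisher's method is defined),
using corrected p-values by default (`use_corrected=False` switches to
raw). Where a TF is scored on several paths of one split, its best
(minimum) p per split enters the aggregate; a TF absent from a split
contributes p = 1. Ranking is descending in X with alphabetical
tie-breaks. A TF's target matrix at time n is taken from the nearest
profiled time point ≤ n. The per-path regulator filter keeps rows with
path_fraction ≥ 0.30 and corrected p ≤ 0.01, both boundaries inclusive.

## TF–TF networks

Nodes are the top 25 TFs of a split by split score; a directed edge t → g
requires a_{g,t} = 1 *and* g among the top 25. Out-degree is capped at 10,
ranked by numeric affinity — by default ranking across *all* targets of t
and filtering to the top set afterwards (the literal reading;
`rank_before_filter=False` gives filter-then-rank). Edge affinity is the
maximal raw single-footprint affinity within the gene's window, falling
back to uniform weights when footprint-level affinities are not supplied.
Node size encodes total target count in six half-open bins
([0,2000), [2000,4000), …, ≥10,000); node color encodes expression
direction vs the reference time with a ±0.1 log2FC dead zone (blue up,
orange down). Export is Graphviz DOT (neato layout) or GraphML.

## SE dynamics

SE calls (≥ 10 kb, optional filter) from all samples merge transitively on
≥ 1 bp overlap, including book-ended intervals — the default semantics of
the standard BED merge utility. Signal is the sum of per-bp coverage over
the full merged span scaled to a fixed library of 1e7 reads; no division
by span length or constituent count is applied, so wider SEs carry
proportionally more signal. Temporal profiles are
`log2((s_t + 1)/(s_ref + 1))`; the pseudocount of 1 guards empty tracks
and is negligible against typical signals (10³–10⁵). An SE is dynamic
when max_t |log2FC| ≥ 1 — direction-agnostic, since both rising and
falling profile classes are real.

Model profiles enumerate all cumulative trajectories with integer steps in
[−2, 2] per transition ((2c+1)^(T−1) candidates); 20 representatives
(paper-silent default) are chosen by greedy max–min Pearson-distance
selection from a seeded random start, constant profiles excluded. SEs
whose maximal |log2FC| is below 1.0 stay unassigned; the rest take the
representative with the highest Pearson r, ties to the lower profile
index. Target assignment searches genes with a primary TSS within
±500 kb of the span's nearest edge and picks the maximum *signed* Pearson
correlation between the SE profile and the gene's expression profile
(enhancer activity and target expression are positively coupled in every
motivating example; `use_absolute_r=True` switches to |r|). Genes with
constant profiles are skipped — their correlation is undefined.

## Synthetic fixtures

The default fixture emulates a differentiation time course at desk scale:
a 1 Mb i.i.d. genome at GC 0.5; 10 TFs with sharply peaked 8 bp motifs
(consensus probability 0.85); 300 footprints of 40–80 bp per time point,
half of them carrying 2 planted consensus copies of one TF; 500 genes over
6 time points whose log2 expression diverges ±3 from time point 1 onward
into an "up" and a "down" group with N(0, 0.1) per-observation noise; one
planted regulator (TF0) targeting 60% of the up-path genes plus a 10%
background rate everywhere (decoy TFs target a 10% random sample); and 40
SEs of 10–30 kb whose coverage follows a designated nearby gene's
expression with N(0, 0.2) log2 noise, at a library size of 1e7.

What the fixtures do *not* emulate: mappability and repeat structure,
footprint width/GC biases that correlate with binding, cooperative or
competitive TF binding, autocorrelated expression noise, replicate
structure, and enhancer–promoter contact constraints. Passing the planted
-recovery tests therefore shows the statistical machinery is correct and
calibrated under its own assumptions — not that the method's error rates
transfer to real chromatin data.

The SE target-recovery tests use genes with independent random-walk
expression profiles rather than the two-group default series: with only
six time points, decoys lying on the same expression path as the
designated target are statistically indistinguishable from it, and the
test would measure tie-breaking rather than recovery.

## Numerical choices and degenerate inputs

- Thresholding requires ≥ 20 background values per TF; the promoter
  baseline automatically raises its sampling depth to meet this.
- Regions shorter than a motif score affinity 0 rather than erroring, so
  mixed-width footprint sets are safe.
- Hypergeometric tails come from `scipy.stats.hypergeom.sf`; Fisher
  aggregation clips p at 1e-300 before the log.
- k-means uses 10 restarts with a seed derived from (base seed + time
  index); all generators take explicit seeds and are pure functions of
  (inputs, seed).
- Empty gene lists, empty networks, all-N sequences, flat SE profiles and
  zero-coverage tracks all return well-defined empty/zero results; errors
  are reserved for contract violations (zero-length regions, overlapping
  bedGraphs, p outside (0,1), missing strands).

## Problem sizes

Defaults were chosen so the full test suite and the calibration script
each complete in seconds on one CPU: 1 Mb genome, 10 TFs, 500 genes,
6 time points, 10,000-region backgrounds, 50-seed recovery experiments,
100-seed SE recovery. All scale linearly in their obvious parameters and
can be raised in `FixtureSpec`/`PipelineConfig` for larger studies.

## Known limitations

- The path model is a deliberate simplification: no probabilistic state
  emissions, no transition model, no gene reassignment across time — a
  gene's path is fixed by its per-step cluster memberships.
- Binding is binarized before association; graded affinity information is
  discarded downstream of thresholding, as in the method implemented.
- The promoter baseline and footprint pipeline share the thresholding
  code path, so a bias in the background sampler would affect both.
- SE target assignment considers correlation only; it cannot distinguish
  a true target from a co-regulated neighbor within ±500 kb.
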