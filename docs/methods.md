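# Methods

This note documents the models, parameter choices and numerical
conventions behind `polyq_netscreen`, and what the synthetic-data tests
do and do not demonstrate about real screen data.

## Touch-response scoring model

A screen record is one RNAi clone: per assayed animal, the number of
tail touches (out of `touches`, default 5) the animal responded to.
Per-animal responsiveness is `100 · responses / touches`; the clone's
responsiveness is the mean over its animals (70–90 in the screen
geometry). The S-score rescales responsiveness by the empty-vector
baseline:

    S = (percent_response − baseline_mean) / baseline_mean

S is a dimensionless relative change: −1 at 0 % responsiveness, 0 at
baseline, and (100 − b)/b at full responsiveness for baseline b. With
the cumulated screen baseline of 20.6 % the maximum is ≈ 3.85. (Screen
write-ups sometimes quote a maximum of 4.55, which corresponds to a
baseline of ≈ 18 %; the formula is used as defined and no fixed maximum
appears anywhere in the code.)

Scoring uses the per-batch (monthly) baseline when one is supplied,
falling back to the cumulated baseline. Per-clone `s_sd` is the sample
SD (ddof = 1) of the per-animal S values, which equals the SD of
per-animal percents divided by the baseline mean. With 5 touches the
per-animal values are discrete (multiples of 20 %); no smoothing or
continuity correction is applied.

### Hit calling

The baseline maps to 0 on the S scale and its SD to
`baseline_sd / baseline_mean` (3/20.6 ≈ 0.146 for the screen values).
A clone is a hit when the whole interval `[s − s_sd, s + s_sd]` clears
the band of ±2.6 baseline SDs around zero — the nearest interval edge
must be strictly outside the band, so a clone exactly on the edge is
`no_effect`. This conservative reading makes the rule much stricter
than a plain 2.6 σ cut on the mean (whose two-sided null tail would be
≈ 0.9 %): because `s_sd` includes the full animal-to-animal spread, a
clone must shift its mean by roughly `s_sd` beyond the band to be
called. The null false-positive rate under Binomial(5, 0.206) sampling
with 80 animals is far below 1 % (measured in the test suite).

Toxicity exclusion precedes scoring: any clone with a phenotype flag is
excluded with the first flag in the canonical order (lethality, larval
arrest, egg-laying defect, developmental delay, morphological
abnormality, other abnormality) as its reason, and never contributes an
S value downstream. Secondary-screen confirmation intersects hit calls
by sign: a clone is confirmed iff it is a hit of the same sign in both
passes.

Gene-level bookkeeping deduplicates clones per gene: a gene is a
modifier if any clone is a hit; a gene with clones of both signs (rare,
none in the synthetic defaults) takes the class of the clone with the
largest |S|.

## Graph-Fourier smoothing

The scored genes' S values are a signal on the functional gene network
restricted to scored genes (induced subgraph; scored genes absent from
the network are kept as singleton components so downstream gene lists
stay complete — a singleton is its own mean and is untouched by
smoothing). The combinatorial Laplacian L = D − W of each connected
component is eigendecomposed densely (`numpy.linalg.eigh`); components
beyond 3000 nodes trigger a warning, as dense decomposition is O(n³).
A normalized-Laplacian variant is available behind a flag.

Edge confidence weights are scaled by the maximum weight before
Laplacian construction, giving weights in (0, 1]. Scaling by the
maximum rather than min-max normalizing is deliberate: min-max maps the
weakest edge to exactly 0, which disconnects its component inside the
weighted Laplacian (a second zero eigenvalue appears and per-component
means are no longer preserved). Min-max normalization to [0, 1] is used
where a true [0, 1] confidence scale is wanted: module edge export for
display, and the confidence-core filter below.

Eigenvalues are frequencies; the first eigenvalue of each connected
component is clamped to exactly 0 (its eigenvector is constant). The
attenuation series zeroes, at level k, the `⌊k · step · (m − c)⌋`
globally highest-frequency coefficients, with m scored genes, c
components, and step = 0.025 over 40 levels. Ranking pools all
components and sorts by eigenvalue, ties broken by (component index,
within-component index) for determinism. Zero-frequency coefficients
are never removed, so level 40 degenerates to per-component means
rather than the zero signal, per-component means are invariant across
levels, and Dirichlet energy x'Lx is non-increasing. Whether the
original analysis ranked frequencies globally or per component is not
recoverable; the global convention is used and the removal schedule is
fully parameterized (`step`, `n_steps`).

## Module detection

Thresholds use the mean and sample SD of the raw (level-0) signal, held
fixed across levels (a per-level-statistics variant is behind a flag;
recomputing per level lowers the threshold as smoothing shrinks the
spread, admitting more noise). Genes strictly above mean + SD form
positive (suppressor-like) candidates, strictly below mean − SD
negative (enhancer-like) ones; no module mixes signs.

Connectivity is evaluated on the high-confidence core of the network:
edges whose min-max-normalized confidence is ≥ `min_confidence`
(default 0.5, i.e. the upper half of the normalized confidence range;
0 disables the filter). Low-confidence links act as bridges between
unrelated above-threshold genes: with a noisy threshold (≈ 13 % of
background genes exceed mean + SD at a 2 SD planted effect), even a
sparse background of weak edges merges distinct modules into one large
component and dilutes them with noise genes. Restricting module
connectivity to confident interactions is the same move as running the
analysis on a core functional network, and planted-module recovery on
the synthetic benchmark is insensitive to the exact cutoff between 0.4
and 0.6. Candidate components of size ≥ 2 (singletons are not modules)
observed at level ≥ 4 are retained when at least 40 % of their genes
remain above threshold at each of at least 2 successive levels
(boundaries inclusive: exactly 40 % and exactly level 4 qualify; both
are flags). The retained module records its extraction level
(`birth_level`) and streak length (`stability_run`).

Redundancy filtering removes, within any pair at Jaccard ≥ 0.8 (flag),
the less preferred module: shorter stability run, then later birth,
then smaller size, then lexicographically larger gene set. The greedy
pass over preference-sorted modules makes the output deterministic.
Annotation attaches, per gene-set collection, the best hypergeometric
terms (see below). Module sizes of 2–50 genes are typical at the
synthetic defaults; sizes outside that range are allowed and logged.

## Enrichment

Upper-tail hypergeometric probability P[X ≥ k] for an overlap k between
a query of size n and a set of size K in a universe of N genes, via
`scipy.stats.hypergeom.sf(k−1, N, K, n)`; the test suite checks it
against draw-by-draw enumeration. The default universe is all genes
assayed and scored in the screen (toxicity-excluded genes omitted),
overridable by file. Raw p-values are reported by default — matching
how screen pathway tables are conventionally printed — with
Benjamini–Hochberg q-values behind a flag (`statsmodels`). The default
minimum overlap is 1, since single-gene pathway hits are meaningful in
small curated collections; 2 is available as a flag. Genes with
multiple clones count once. GO-style annotation supports the true-path
rule: a DAG of `is_a` edges (child → parent, as `obonet` produces) is
transitively closed per gene; the closure is idempotent and
annotations only grow. Frequent-category counting filters terms below
18 query genes by default.

## Cross-species intersection

Worm modifiers expand to mouse genes through an ortholog-cluster table
(many-to-many allowed; worm genes without orthologs are logged).
Counting happens at the mouse-gene level — a mouse gene counts once
however many worm genes map to it. Each conserved gene is classified
against two dysregulation tables (direction up/down, one direction per
gene per table, conflicts rejected): present in A only, B only, both
concordant, or both opposite; the four categories partition the
dysregulated conserved genes. Direction is categorical; fold-change
magnitudes are out of scope. The default prioritization rule
(`suppressor_up`) flags genes whose RNAi knockdown suppresses worm
neuron dysfunction and that are up-regulated in at least one mouse
model — genes whose excess activity tracks disease and whose inhibition
is protective, hence candidate inhibition targets.

## Synthetic data generator

All generators are pure functions of (parameters, seed), with
independent named substreams so adding one generator never perturbs
another. Defaults encode the screen geometry: 5 touches, 70–90 animals
per clone, baseline 20.6 %, baseline SD 3 %, 500 genes, three planted
10-gene modules at ±2 baseline SDs, planted-partition network with
within-module edge probability 0.6 and background 0.01, within-module
confidence weights Uniform(0.5, 1] versus background Uniform(0, 0.5],
and a spanning path guaranteeing each planted module is connected.

Per-animal responses are Binomial(5, p) with p the gene's true
responsiveness plus a per-well Gaussian jitter of SD 2.2 %. The jitter
models plate/day effects: binomial sampling alone at ~80 animals gives
a between-clone SD of only ≈ 2 %, while the observed screen baseline SD
is 3 %; 2.2 % well-level variation brings the total to ≈ 3 %
(√(2.0² + 2.2²)). On the S scale the resulting background noise SD is
≈ 0.146, so the ±2 SD planted effects sit ≈ 2 noise SDs from zero —
deliberately too weak to be called as single-clone hits by the 2.6 SD
band, which is the regime where network smoothing adds value. A
beta-binomial-free design was chosen for transparency; toxicity flags
are assigned at random to a configurable fraction of background clones
(never to planted genes), not modelled mechanistically.

Mock annotation collections contain one exact term per planted module
(a perfect positive control) plus random terms. Cross-species fixtures
come in two forms: a standalone table set whose intersection counts are
fixed by construction (defaults: 662 modifiers, 239 conserved, 49
dysregulated in ≥ 1 model, 6 oppositely, 12 suppressor-up), used to
test the counting logic; and a truth-linked set tied to the simulated
screen's own genes, used by the `simulate` subcommand so the emitted
input files form one coherent study.

What passing synthetic tests show: the scoring arithmetic, filter
semantics, spectral identities and counting logic are correct, and the
full chain can recover planted modular signal at realistic noise. What
they do not show: performance on real functional networks (degree
heterogeneity, hubs, confidence miscalibration), real RNAi off-target
structure, batch drift beyond i.i.d. well jitter, or the specific
module counts of any published screen.

## Problem sizes and numerics

The test suite and benchmarks use 30–500-gene graphs — sizes where
dense per-component eigendecomposition is instantaneous and exact
identities (round-trip to 1e−8, Parseval to 1e−9, energy monotonicity
to 1e−9) can be asserted tightly. Floats are written to TSV at 6
significant digits; all tables have stable column and row orders;
reruns of the pipeline on identical inputs produce byte-identical
artifacts (hash-verified in the run manifest).

## Known limitations

- Dense eigendecomposition limits practical component size (warning at
  3000 nodes); no Chebyshev/approximate filtering is provided.
- The stability filter matches modules across levels by gene content
  against the next level's above-threshold set; no explicit lineage
  tracking of merges/splits is attempted.
- The hit-band interpretation ("S ± SD outside baseline ± 2.6 SD")
  treats the baseline SD on the S scale; applying it on the percent
  scale would rescale the band by the baseline mean.
- Ortholog mapping treats clusters as flat gene pairs; paralog
  weighting is out of scope.
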