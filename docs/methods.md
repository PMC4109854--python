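# Methods

This note documents the models and procedures implemented in `regulonscan`,
the parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical and design choices made where the design was
genuinely open.

## Search-space delineation

Each gene receives one candidate window per transcript TSS:
`[TSS-500, TSS)` on the gene's strand, or `[TSS-5kb, TSS+5kb)` /
`[TSS-10kb, TSS+10kb)` symmetric around the TSS. All coordinates are
0-based half-open (BED convention); the inclusive interval notation used in
the literature maps to half-open intervals of identical length. Windows of
the same gene are merged where they overlap; the span of any *other* gene
truncates a window at its nearest boundary, regardless of that gene's
strand (the simplest reading of the truncation rule — strandedness changes
only which boundary is "begin" vs "end", not the cut position); the
downstream halves of the symmetric windows are truncated by the same rule.
Coding exons of every gene, the window's own gene included, are subtracted,
which may split a window into several regions or consume it entirely.
Fragments shorter than 10 bp are dropped (the sources are silent on a
minimum; 10 bp is below any scoreable motif width, so the choice cannot
affect rankings). Windows are strictly TSS-bounded: intronic sequence
beyond the window is never added.

## Homotypic cluster scoring

A region is scored for clusters of a *single* PWM under a two-state
generative model: background emits bases from a 0-order model; a cluster
emits motif sites (either strand) separated by background gaps whose
lengths are geometric with mean `gap_expectation` (default 35 bp). The
reported score is the log2 likelihood ratio of the best cluster versus pure
background. Background-emitted bases cancel in the ratio, so a cluster of
sites at starts q_1 < ... < q_m scores

    sum_j siteLLR(q_j)
  + sum_{j>=2} [ log2 p + (q_j - q_{j-1} - W) log2(1-p) ]   with p = 1/(1+gap_expectation)
  - cluster_open_bits

where `siteLLR` is the site's log-odds under the pseudocounted PWM
(pseudocount 0.375 per cell, the scanner's conventional default) against
the background. The maximum over all placements is found exactly by a
linear-time dynamic program (the gap cost is affine in position, so a
running maximum suffices); a Viterbi-style max is used rather than a
forward sum over site configurations — a deliberate simplification that
keeps the score oracle-checkable by exhaustive enumeration while preserving
the likelihood-ratio semantics. Scores are clamped at 0 (an empty cluster
is always admissible), matching a cluster-score threshold of zero so that
*every* region receives a score.

Parameters and defaults:

| parameter | default | meaning |
|---|---|---|
| `gap_expectation` | 35 bp | mean within-cluster gap; sets the geometric penalty slope |
| `pseudocount` | 0.375 | additive count per PWM cell |
| `cluster_open_bits` | 4.0 | log2 prior odds against opening a cluster (one site must beat ~1/16 odds) |
| `background` | per-region | 0-order frequencies from the scanned sequence, +1 pseudocount per base |

The background is strand-symmetrised (A/T and C/G averaged) so that
both-strand scores are exactly invariant under reverse complementation of
the region — a property the test suite asserts, and which a raw
composition estimate would break. A global background may be supplied
instead. `N` bases emit under both models and contribute zero log-odds.
Motifs shorter than 4 columns are rejected. The batch scanner is a numba
kernel; a pure-Python reference DP with traceback (site list, cluster
interval) serves the single-region API and is cross-checked against the
kernel in tests.

## Cross-species rank aggregation

Per species, regions are ranked by descending cluster score (ties broken by
a seeded shuffle); a gene's ratio in a species is its best region's rank
divided by the number of ranked regions in that species (this denominator
keeps the marginal uniform when species differ in coverage). The sorted
ratios r_(1) <= ... <= r_(K) aggregate to the order-statistic probability

    Q = K! V_K,   V_0 = 1,
    V_k = sum_{i=1..k} (-1)^(i-1) V_{k-i} r_(K-k+1)^i / i!

i.e. P(U_(i) <= r_(i) for all i) for K iid uniforms — the chance of a rank
configuration at least this good. The alternating recursion is numerically
benign for the K <= 10 used here (terms are bounded by x^i/i!); Q is
clamped into (0, 1]. Species without data for a gene are dropped (K
reduced) rather than imputed at ratio 1, which would penalise genes lacking
an ortholog for reasons unrelated to regulation. Genes are ordered by
ascending Q; genes with score zero in every species are appended in
seeded-random order, and ties in Q are broken by a seeded shuffle of the
tied block, so a ranking column is always a permutation of 1..G and a
stored seed reproduces it bit-identically.

Track rankings score each gene by the maximum peak `signalValue` over all
peaks overlapping (>= 1 bp) any of its regions; zero-overlap genes go to a
seeded-random tail.

The on-disk database is a binary rank matrix (`.rankdb`) plus a JSON
sidecar (`.meta.json`) with the universe, features, seed, parameters and a
SHA-256 of the universe; a TSV export exists for inspection. Databases are
rebuilt, never incrementally updated.

## Recovery enrichment

With T = ceil(top_fraction * G) (default top_fraction 0.03) and set size s,

    AUC = sum_{k=1..T} c(k) / (T s)

where c(k) is the number of input genes at rank <= k. The normalisation
constant T*s bounds AUC below 1 (a perfectly top-ranked set reaches
1 - (s-1)/(2T)). NES is the z-score of a feature's AUC against all AUCs of
its own collection, using the sample (n-1) standard deviation
(configurable); motif and track collections are normalised separately, so
identical ranking columns in two collections give identical AUCs but
independently calibrated NES. A collection needs >= 3 features; if all
AUCs are identical the NES degenerates to 0 with a warning. Note the NES
ceiling for small collections: with n features the z-score cannot exceed
(n-1)/sqrt(n), so the default threshold of 3.0 presumes a collection of
dozens of features or more. Features with NES >= 3.0 (default) are
reported; at that threshold the empirical false-discovery behaviour of the
original large-collection studies is in the few-percent range.

The leading edge of a reported feature is the smallest rank k* <= R
(default rank threshold R = 5000, recorded in metadata; a conservative
top-of-ranking bound) maximising c(k)/s minus the collection background
b(k) = mean + 2 population SDs of all features' recovery fractions at rank
k. The candidate itself is included in the background (the envelope is
descriptive, not an estimator). Input genes ranked above k* are the
feature's candidate targets; if the difference never exceeds 0 the target
set is empty. Ties at the argmax resolve to the smallest k — the more
conservative target set.

## motif2TF mapping

The association graph is undirected and typed: annotation edges (motif to
TF, tagged with the species of the annotation), homology edges (TF to TF,
percent identity) and similarity edges (motif to motif, p-value). Edge
filters apply before traversal: identity >= `min_identity_pct` (default 0)
and similarity p <= `max_similarity_p` (default 0.001; the "similarity
FDR" and "similarity p-value" thresholds quoted in different places are
treated as the same number). A path uses exactly one annotation edge, at
most one similarity edge (before the annotation) and at most one homology
edge (after it); chaining two indirect edges of the same type is
disallowed — every documented path pattern respects this, and it prevents
unbounded transitive drift. TFs annotated for a species other than the
target species are traversable but are not themselves candidates (the
candidate list for a motif annotated only in another species consists of
that TF's target-species homologs).

Candidates are ranked by tier — direct annotation, TF encoded by an input
gene, homology, similarity — then by shorter path, higher identity, lower
similarity p, and finally lexicographic TF id (the original tie-break being
unspecified, lexicographic makes output deterministic). Because tightening
the p threshold removes the worst similarity edges first and a candidate's
best path is by definition its last to go, filtering can remove candidates
but never reorders survivors.

The native motif similarity (max over ungapped offsets and both
orientations, >= 5 overlapping columns, of the mean per-column Pearson
correlation of pseudocounted probability columns; empirical p from
column-shuffled copies, p = (1 + #{shuffled >= observed}) / (1 + n)) is a
deterministic, seeded stand-in for an external alignment tool's p-values;
importing a precomputed similarity table is the recommended production
path. Degenerate (zero-variance) columns correlate as 0.

## Regulons, meta-regulons, and the leading-edge test

A feature's targets accrue to *every* candidate TF of that feature; per TF,
target sets union with per-target supporting-feature counts, and the
regulon's NES is the maximum over its features. Features with no TF
candidate are kept as orphan regulons (an enriched motif with no known TF
is still a finding). Across a batch of gene sets, a TF's meta-regulon
counts, per target gene, the number of gene sets in which the TF was
enriched and the gene fell in its optimal target subset — once per gene
set, not once per feature — with a minimum-recurrence filter.

For validating predicted targets against an external ranking, the
leading-edge test maximises d(k) = c(k)/s - k/G (the unweighted
recovery-vs-uniform difference; the unweighted form is the one consistent
with counting members hypergeometrically), takes k* = argmax (smallest on
ties), x = c(k*), and reports the upper hypergeometric tail
P[X >= x], X ~ Hypergeom(G, s, k*). **Caveat:** because k* is chosen to
maximise the difference, this p-value is a maximum-selected scan statistic;
under a null of shuffled sets its distribution is anti-conservative
(median ~0.1-0.2, not uniform). It is a descriptive measure of observed
enrichment strength, not a calibrated test; treat absolute values
accordingly.

## The synthetic-data generator

The generator emulates a planted-signal validation study: genes laid out on
artificial chromosomes with margins wide enough that each gene keeps one
clean upstream region (500 bp by default, coinciding with the `up500`
delineation of the generated annotation — asserted in tests); background
sequence from a 0-order model at 42% GC; a true motif of 12 columns at 1.6
bits/column (dominant-base columns); decoys half column-shuffled from the
true motif (same composition, scrambled order — the adversarial case) and
half Dirichlet-random; target genes carrying 1 + Poisson(2) planted sites
with uniform spacing jitter, each site sampled from the motif and then
degraded at a per-target rate drawn uniformly from [0, 0.25] (ChIP-derived
positive pools are graded in binding strength; a graded pool is what makes
target-selection sensitivity informative); "orthologous" species derived by
per-base substitution at 30% outside planted sites and 5% inside them, with
no indels, so cross-species region mapping is the identity and orthology
resolution is out of scope; peak tracks placing strong peaks
(signalValue 50-150) on planted regions plus Poisson background peaks
(1-30) on all regions; and input gene sets at noise fractions
0/0.25/0.5/0.75/1, where noise genes *replace* true targets at fixed set
size (fixed s keeps AUCs comparable across fractions; an append mode can be
had by raising `set_size`). Everything, including file bytes, is
deterministic given the seed.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: higher-order sequence composition (CpG islands,
repeats), conserved non-regulatory elements (here, conservation contrast
exists only at planted sites, so cross-species aggregation is more
informative than in real genomes), indels and rearrangements between
species, heterotypic site clustering, fragment-level ChIP artefacts, and
the size/diversity of real motif collections (thousands of PWMs vs dozens
here — NES calibration on real collections rests on a much richer AUC
background).

### Study conditions used by the validation experiments

* Planted-signal recovery: G = 1000 genes, 20 targets, 1 true + 49 decoy
  PWMs, 3 species, input = the 20 targets; 20 seeds. The true motif is
  required at NES rank 1 with NES >= 3 in >= 95% of seeds.
* Noise robustness: G = 7000, a 200-gene target pool, input sets of
  s = 200 at each noise fraction, 10 seeds, database built once per seed.
  G is chosen so that T = 0.03 G = 210 >= s, the geometry of top-200 target
  sets in a genome-scale universe (where T ~ 670); with a small universe
  and s > T every feature that ranks planted genes anywhere near the top
  saturates the same AUC ceiling and the comparison degenerates.
  Sensitivity is recall of the *full* target pool (dilution must cost
  recall); PPV is the precision of the selected targets; runs where the
  true motif is not reported count 0 for both.

## Numerical choices and degenerate inputs

Seeded `numpy` Generators drive every stochastic step; per-column seeds are
spawned via `SeedSequence` so feature order does not perturb other columns.
Equal cluster scores, equal q-values and zero-score tails are all resolved
by seeded shuffles — never by input order. Empty gene sets, gene sets
disjoint from the universe, collections of fewer than 3 features, motifs
shorter than 4 columns, and PWM/region alphabet violations raise
immediately; unknown genes in an input set are dropped with a warning.
Manifests omit wall-clock timestamps by default so identical runs produce
byte-identical manifests (an `include_timestamp` flag adds one); input
files are recorded by SHA-256.

## Known limitations

* The cluster score maximises over site placements instead of summing over
  them; scores are therefore slightly conservative for diffuse clusters of
  weak sites relative to a forward-sum formulation.
* The native motif-similarity p-value is empirical (resolution 1/(1+n));
  production use should import precomputed similarity tables.
* The leading-edge hypergeometric p-value is not null-calibrated (see
  caveat above).
* NES thresholds presume reasonably large feature collections; with fewer
  than ~12 features NES >= 3 is unattainable by construction.
* Meta-regulons count recurrence per gene set; alternative weightings (per
  feature, NES-weighted) are not implemented.
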