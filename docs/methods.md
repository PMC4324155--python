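# Methods

## Coordinate conventions and digestion

All coordinates are 0-based half-open. BED input is read natively; SAM
POS is converted on ingest, and a reverse-strand read's 5' end is its
rightmost aligned base. In-silico digestion scans every position of
each chromosome for exact, case-insensitive occurrences of the enzyme
motif (overlapping occurrences included) and cuts at
`match_start + cut_offset`; HindIII (A^AGCTT: motif `AAGCTT`, offset 1)
is the named default. Fragments therefore partition each chromosome
exactly, which makes read-to-fragment assignment a binary search and is
asserted as an invariant whenever a fragment map is constructed.

Per-fragment GC content excludes ambiguous bases from both numerator
and denominator; a fragment with no unambiguous base gets 0.5, flagged
imputed, rather than an undefined 0/0. Mappability defaults to 1.0 so
the normalization degrades gracefully to length+GC when no mappability
track is supplied; when a scored track is given, a fragment's
mappability is the score-weighted mean over its bases with uncovered
bases contributing 0.

Gene-fragment association uses a >= 1 bp shared-overlap rule with no
minimum-fraction threshold; the window parameter of node-feature
mapping exposes flanking-region behavior where wanted.

## Valid-pair filtering

Three standard criteria are applied before contact counting, each as a
pure row predicate so the result is independent of input order:

1. both ends in the same fragment (dangling ends / self-circles);
2. adjacent fragments on one chromosome (re-ligation artifacts);
   inter-chromosomal pairs always pass this filter;
3. a read 5' end farther than `max_cut_distance` (default 800 bp) from
   the nearest end of its fragment, applied per end.

Removed categories plus kept pairs sum exactly to the ingested pair
count, and the filter report records every tally. Survivors are
deduplicated into per-fragment-pair counts with canonical id order.

## Neighborhood construction

Starting from the seed genes (level 0), each iteration takes the
current frontier, follows contacts from the frontier genes' fragments
to mate fragments, and maps those onto genes; supported gene pairs
become edges and newly reached genes form the next frontier, up to the
level parameter `L` (default 1). Two facts make this implementable as
one breadth-first search over a precomputed gene-pair support table:
node levels equal hop distance from the seed set, and an edge is
discovered exactly when one endpoint has level <= L-1. Same-level
lateral edges are retained when discovered. Mate fragments overlapping
no gene are dropped and tallied, keeping the graph gene-centric.

Edge weight is the total contact count over the distinct fragment
pairs joining the two genes; a contact row whose two fragments each
overlap both genes contributes once, not twice, to that pair. A
`min_edge_weight` threshold (default 1) is exposed because deeper real
libraries need > 1 to suppress ligation noise. Expansion iterates genes
in lexicographic order and serialization sorts rows, so two runs on
identical input produce byte-identical node/edge tables.

## Edge normalization and scoring

Counts are modeled as Poisson with log link on the product covariates
of the two genes' fragments: total fragment length (sum), GC and
mappability (length-weighted means, clamped to [1e-3, 1] before the
log). The fit is IRLS to relative tolerance 1e-8 (at most 100
iterations) with explicit errors for < 10 observations, exact
collinearity (the offending pair is named) and non-convergence. The
per-edge score is the upper-tail probability P(X >= observed | mu_hat)
— stated explicitly in output headers, since a model-based "edge
probability" would be a different quantity — with Benjamini-Hochberg
adjustment across the graph's edges and a configurable significance
level (default alpha = 0.05).

Calibration caveat: for a discrete Poisson tail, P(p < alpha) <= alpha
and the gap is large at small means (at mu = 3 the achieved level is
~0.034). Calibration checks therefore run at count scales where the
tail is near-continuous (means around e^4.5); at typical Hi-C edge
counts of 1-20 the scores are conservative, which errs on the side of
fewer false translocation calls.

## Contact distance and graph comparison

The contact distance between two genes is the shortest-path hop count
using only edges with q < alpha (alpha = 1 admits every edge);
unreachable is reported explicitly and is treated as "distance >= 2"
in case/control contrasts, since the claim being tested is the absence
of a direct significant contact. The per-edge significance filter is
one reading of "k significant contacts apart"; a path-level composite
probability would be an alternative and is intentionally not mixed in.

Graph comparison converts both graphs to binary adjacency matrices
over the union of their node sets and correlates the flattened strict
upper triangles; identical graphs return exactly 1.0 (short-circuited
before floating-point round-off), and constant adjacency vectors
(empty or complete graphs) raise rather than returning NaN. A weighted
variant is available behind a flag.

## ERGM estimation

Change statistics follow the standard definitions: `edges` -> 1,
`nodecov(a)` -> a_i + a_j, `absdiff(a)` -> |a_i - a_j|, `triangle` ->
common-neighbor count of the dyad, `twopath` -> deg_i + deg_j computed
without the dyad edge (term definitions vary across implementations;
this one makes the graph statistic Σ_v C(deg_v, 2)). Estimation is
logistic regression of dyad indicators on change statistics (MPLE),
which *is* the exact MLE for dyad-independent term sets and a standard
approximation for triangle/twopath. Degeneracy — empty or complete
graphs, perfect separation, estimates diverging past ||theta|| = 30 —
is a first-class error, never a silent huge coefficient.

`exact_mle_small` enumerates all graphs on <= 5 nodes (<= 2^10), forms
the exact normalizing constant, and maximizes the likelihood by damped
Newton iteration to 1e-8, with standard errors from the inverse Fisher
information (the covariance of the statistics under the model). It
exists as an independent verification route for the MPLE and is never
used as the production estimator. Simulation draws dyads independently
at their conditional probabilities for dyad-independent models and
falls back to Gibbs sweeps over dyads otherwise (configurable burn-in
and thinning), reproducibly under a fixed seed.

## Synthetic data generator

The generator emulates a two-condition Hi-C comparison at desk scale.
Defaults — the package's study conditions — are: two 300 kb
chromosomes; mean fragment length 3 kb (geometric cut-site spacing,
minimum 200 bp); 40 non-overlapping genes of 4-12 kb placed uniformly;
20k read pairs (100k in translocation screens); intra-chromosomal pair
rate proportional to separation^-gamma with gamma = 1.0; flat
inter-chromosomal rate 0.01 in kb^-gamma units, which puts roughly a
tenth of read pairs between chromosomes, a realistic Hi-C share;
covariate exponents (0.5, 0.3, 0.2) on fragment length, GC and
mappability products, scaled to mean 1 so they modulate but do not
redefine the base rates; GC per fragment from Beta(20, 20) and
mappability from Beta(10, 2). A planted translocation multiplies the
rates of all fragment pairs joining two named genes (default 50x).

Same-fragment and adjacent-fragment pairs are excluded from the rate
model: the generator emulates valid post-filter contacts, and the
filters themselves are exercised on handcrafted fixtures. Read 5' ends
are placed within 500 bp of a fragment boundary, mimicking
ligation-junction geometry, so the cut-distance filter reflects real
read placement. Sequence realization draws bases per fragment at that
fragment's target GC, stamps the enzyme motif at every cut site and
mutates accidental motif occurrences away (never touching a stamped
window), so digesting the emitted FASTA reproduces the intended
fragment map exactly; fragment-level GC covariates are the drawn
targets, which the realized sequence tracks closely (r > 0.9).

What the generator does **not** emulate: TAD/compartment structure,
PCR duplicates, mapping errors, copy-number variation, or
FASTQ-level read sequences. Passing tests therefore demonstrate the
correctness and statistical behavior of the algorithms under the
stated rate model, not robustness to every artifact of real libraries.

Case/control pairs share one scaffold (genome, fragments, genes,
tracks) and draw read pairs from independent streams spawned from the
same seed; the control sets every translocation multiplier to 1.

The distance-decay diagnostic bins intra-chromosomal fragment pairs by
mid-to-mid separation (log-spaced bins from 5 kb), normalizes observed
counts by the number of eligible pairs per bin, and fits a log-log
least-squares line; its slope estimates -gamma directly because the
covariate factors average out within bins.

## Problem sizes and numerical choices

Property checks run at the sizes stated above: 50 random instances for
builder-oracle equivalence; 200 replicates of n = 2000 for GLM
recovery (3 SE criterion); 2000 edges for null calibration against the
binomial 99% band; all connected non-complete graphs on 4 and 5 nodes
for MPLE-vs-enumeration agreement at 1e-4 (complete graphs are
excluded because their MLE is non-finite — degeneracy is the asserted
behavior there, on both routes); 100 replicates for covariate-sign
recovery; 20 seeds at 100k pairs for the translocation contrast. These
sizes keep each check well-powered while the whole suite remains a
desk-scale run.

Known limitations: MPLE standard errors for triangle/twopath models
are the usual logistic approximations, not MCMC-MLE errors; the GLM
fits observed edges only (zero-count candidate pairs can be supplied
as a background table but are not imputed); merge of two graphs drops
edge scores wherever the inputs disagree, requiring a re-score.
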