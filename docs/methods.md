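# Methods

This note documents the models and procedures implemented in `hicevo`, the
choices made where the underlying methods are under-specified, what the
synthetic data emulate, and the package's known limitations.

## Contact matrices and normalization

All analyses run on symmetric intra-chromosomal matrices of binned contact
counts (10-, 20- and 100-kb working resolutions; 0-based half-open bin
coordinates). Bins with zero marginal in the raw matrix are masked and stay
masked through every normalization — they would otherwise produce
divide-by-zero artifacts in balancing and O/E.

**Balancing.** `kr_balance` finds per-bin weights *w* such that
`w_i · M_ij · w_j` has equal row sums over unmasked bins, the contract of
Knight–Ruiz-style matrix balancing. The implementation is a damped symmetric
Sinkhorn iteration, `w ← w · rowsum^(−1/2)`, run to a relative row-sum
tolerance of 1e-10 by default (3000-iteration cap; non-convergence raises
with the final residual). The balanced matrix is rescaled so its total
equals the raw total, keeping downstream medians on a count-like scale. The
test suite checks the fixed point against an independent *alternating*
Sinkhorn oracle; the two iterations agree to better than 1e-6 on random
matrices of 20–100 bins.

**Expected-by-distance.** `E(d)` is the median (default, the conventional
choice) or mean of unmasked pixels at separation *d*. On sparse matrices the
per-distance median is 0 for most strata — any stratum whose per-pixel mean
falls below ln 2 has a zero median under Poisson noise — so every pipeline
step that feeds on O/E at realistic desk-scale depth uses the mean
estimator; the median remains available and is what a deeply sequenced map
would use. An optional per-bin domain id excludes within-domain pairs from
the strata, giving a background free of TAD-level enrichment; aggregate TAD
maps are computed against this background so that their contact ratio
estimates the domain enrichment itself rather than a mixture.

**Down-sampling and quantile normalization.** Down-sampling is binomial
thinning of upper-triangle counts (exactly the distribution of subsampling
reads), reproducible per seed. Quantile normalization operates on the
upper-triangle values of bins unmasked in *all* matrices and assigns the
rank-wise mean with stable tie-breaking, so the sorted value multisets of
the outputs are identical by construction.

## A/B compartments and the A-B index

Step one works at 100 kb: PC1 of the column-centered O/E matrix (the
`prcomp` convention), oriented by the Pearson correlation between PC1 and
per-bin gene counts — gene-dense bins are A. A constant PC1 raises a
degenerate-input error; an exactly zero correlation raises an
ambiguous-orientation error rather than guessing.

Step two scores each 20-kb bin by its observed/expected contact with the
low-resolution A regions versus the B regions (labels broadcast from the
covering 100-kb bin; the bin itself excluded): `ab_index = A_score −
B_score`, positive meaning A-like. Three estimators of the per-bin score are
provided:

- `aggregate` (default): Σ observed / Σ expected over all member bins — the
  inverse-variance-weighted estimate under Poisson counting, stable at any
  depth;
- `region`: median over contiguous low-resolution regions of each region's
  ratio of sums;
- `bin`: median of per-pixel O/E over member bins — the textbook form,
  appropriate only for deeply sequenced maps (at 10⁵ contacts on a 40-Mb
  chromosome most pixels are empty and this median is identically zero).

Score tracks get a 3-bin (60-kb) NaN-aware running mean by default
(`smooth_bins=3`). Compartments are megabase-scale, so this smoothing
reduces per-bin counting noise at negligible bias; it is disabled by passing
1. With these defaults, planted compartment signs are recovered on ≥ 97 % of
bins (rank-separation AUC ≥ 0.997) at 10⁵ contacts per chromosome.

**Evolutionary states.** Reference 20-kb bins whose intervals lift
reciprocally into every query species form a bins × species A-B matrix; the
query value is read at the bin containing the lifted interval midpoint.
States come from K-means over this matrix. The state count defaults to 7;
`choose_state_number` implements the SSE-elbow rule (the k maximizing the
discrete second difference of SSE over the candidate range) as a diagnostic,
but on noisy A-B matrices a smooth convex SSE curve maximizes the second
difference at small k, underestimating the state count and leaving states
impure, which inflates the conserved fraction. Externally computed state
assignments (e.g. from a phylogenetic hidden-Markov model with Gaussian
process emissions) can be fed to `group_states` directly in place of the
K-means labels.

**Grouping.** A bin has A status when its A-B index is positive (the natural
zero of the difference score). Per state and species, the fraction of
A-status bins is computed; all species > 0.90 ⇒ CA, all > 0.70 ⇒ WCA,
symmetric on B fractions for CB/WCB, else NC — thresholds are open bounds.
An NC state is flagged human-specific-A when the reference fraction exceeds
0.70 while every other species is below 0.50 (both configurable); this
operationalizes "A in human, B elsewhere" without inventing a precise
published cut.

## TAD calling

Raw insulation of bin *i* is the mean of the 13×13-bin square (260 kb at
20-kb bins) of contacts passing over *i*; the normalized score is
log2(raw / chromosome mean over defined bins), making it invariant to global
scaling. The delta vector compares the mean score over the 5 bins (100 kb)
left of *i* with the 5 bins right — the 200-kb delta span is read as a
*total* span, half per side; the per-side reading blurs adjacent minima once
TAD size approaches the window and measurably loses boundaries. A boundary
is a positive-to-negative delta zero crossing; because the crossing sits 1–3
bins off the insulation minimum for asymmetric wells, the reported bin is
the score minimum within ±3 bins of the crossing (exact, no margin of
error). Strength is the local delta maximum left of the boundary minus the
local minimum right of it, both within the delta span; crossings under the
0.5 noise threshold are dropped. TADs tile the chromosome between
consecutive boundaries (≥ 3 bins; no nesting); terminal half-open segments
are excluded by default since they lack a flank.

**TAD strength** is the median over distances d = 1 … L−1 bins of
(median intra-TAD contact at d) / (median TAD-vs-neighbor contact at d),
the neighbor region being the TAD extended by its own length on each side,
clipped to the chromosome. Distances with a zero inter median are skipped;
if all are zero the strength is undefined and an error is raised. On planted
domains with 2× enrichment the median strength across TADs falls in
1.6–2.0 — medians of small Poisson counts are integer-valued, which biases
individual ratios but keeps the cross-TAD median near the planted value.

**Conservation.** Reference boundary positions lift through per-species
homology maps (reciprocal blocks only; a boundary in a map gap is
unclassified — absence of alignment is not evidence of divergence). Distance
to the nearest query boundary ≤ 40 kb ⇒ conserved with that species;
≥ 100 kb ⇒ specific; the 40–100-kb zone is unclassified. Species-conserved
requires a conserved verdict against every query; human-specific requires a
specific verdict against every query. TADs are Cons when both flanks are
species-conserved and HS when at least one flank is human-specific.

## Promoter–enhancer interactions

Promoters span TSS −2200/+500 bp (strand-mirrored; a window straddling two
10-kb bins anchors at the bin containing the TSS). For each promoter anchor,
every unmasked bin within ±10 Mb and ≥ 20 kb away is tested. The background
replaces an external hierarchical domain model with a one-parameter-per-
domain form: expected(i,j) = E(|i−j|) · f_T, where E is the mean-estimator
decay of the matrix and f_T is the median O/E inside the TAD containing the
pair (1 outside TADs). Significance is the upper Poisson tail
P(X ≥ observed) at that expected value, computed **on the raw count
matrix** — balanced values are not counts, and a count model applied to
them has no calibration — with Benjamini–Hochberg FDR over all
promoter-centered tests jointly. Retained PEIs satisfy FDR ≤ 0.001 and
length ≥ 20 kb; pairs whose distal bin overlaps any promoter window are
dropped (the promoter–promoter filter). Under null simulations (planted
loops absent) the realized false-discovery proportion across 50 seeds is 0 —
the discrete Poisson tail is conservative.

Enhancer bins are annotated against regular-/super-enhancer peak sets when
the overlap exceeds 5 kb or half the bin; SE takes precedence over RE (SE
peaks subsume REs in standard pipelines). APA averages the O/E submatrix
around each eligible pixel; the score is the center value over the mean of
the corner block in the lower-left (short-distance) quadrant, with > 1
indicating enrichment.

**Conservation.** Both anchors must lift reciprocally onto 5–20-kb intervals
of one query chromosome, with the lifted promoter within 20 kb of the
annotated homologous promoter; failures are recorded by reason (unmapped,
not reciprocal, size out of range, trans split, promoter displaced) and make
the PEI unclassified. The distance judgment computes the Euclidean distance
in (promoter-midpoint, enhancer-midpoint) space to the closest query PEI of
the homologous promoter and passes when d < min(0.2·|i−j|, r2), r2 = 20 kb
for the conservation test and 50 kb for the specificity test (no query PEIs
⇒ d infinite). The enrichment judgment passes when the lifted pixel's
observed − expected strictly exceeds the genome-wide 20th percentile of the
query species' own PEI enrichment scores. Per species, conserved-vote =
distance pass (20 kb) OR enriched; specific-vote = NOT near (50 kb) AND NOT
enriched; species-conserved/human-specific require unanimity, anything else
is unclassified.

**Enrichment statistics.** The HAR permutation test redraws same-size
enhancer-bin sets from the universe without replacement;
p = (1 + #{null ≥ obs}) / (1 + n_perm). Because the statistic (fraction of
bins containing a HAR) is discrete, this p is conservative at ties; a
randomized tie-broken variant (`tie_break="randomized"`), exactly uniform
under the null, is provided and used for calibration studies. SNP enrichment
and TAD gene-composition contrasts use Fisher's exact test on 2×2 tables.

## Expression normalization and contrasts

TPM tables of single-copy orthologs are log2(TPM+1)-transformed
(pseudocount configurable; 0 makes multiplicative factors exact log shifts).
Genes inside every sample's interquartile range are ranked within samples;
the 1000 genes with the lowest across-sample rank variance are the anchors
(all eligible genes, with a warning, when fewer qualify). Each sample is
shifted so its anchor median equals the cross-sample mean of anchor medians
— a symmetric common value with no designated reference sample. The
procedure is idempotent and removes planted library-scale factors to within
2 % under the default simulation; residual error comes from cross-species
expression divergence leaking into the anchor medians, which the
rank-conservation selection suppresses but cannot eliminate.

Cross-species variation is the per-gene CV (sd/mean, ddof 1) of species-mean
expression; genes with zero mean are undefined. Class contrasts report the
reference-vs-others log-fold difference with a one-sample t test and,
given pairwise divergence times, fit correlation-vs-time with
`a·exp(−b·t) + c` by nonlinear least squares (bounded, b ≥ 0).

## TF-pair framework

TF preference between PEI classes is Δ = (−log10 p_HS) − (−log10 p_Cons)
computed from externally supplied motif-enrichment p-values (floored at
1e-300), with |Δ| > 5 strict. Candidate enhancer-TF/promoter-TF pairs
require ≥ 3 motif occurrences in the role, TPM > 1, and a PPI path of length
1 (direct) or 2 (indirect, one intermediate). Per-PEI co-occurrence is a
binary indicator (enhancer-TF hits the enhancer AND promoter-TF hits the
promoter); the preference test is a one-sided Mann–Whitney U (HS > Cons),
computed by full permutation enumeration when the assignment count permits
(tie-safe and exact; matches brute-force enumeration at all small n) and by
the tie-corrected normal approximation otherwise. No multiple-testing
correction across pairs is applied, matching the published cutoff; under
label permutation the kept-pair rate stays at the nominal level.
Binding-site conservation compares per-TF phastCons score sets between
classes with a two-sided rank-sum test.

## Synthetic data: what it emulates and what it does not

Expected intensity per pixel:
`μ(i,j) ∝ (1+|i−j|)^(−α) · exp(β·s_i·s_j) · γ^[same TAD] · λ^[loop pixel]`,
scaled so the upper-triangle total equals the target depth, with
counts ~ Poisson(μ). Defaults are the study conditions used throughout the
tests: a 40-Mb chromosome; depth 10⁵ contacts; α = 1; β = ln 2 ⁄ 2 (a 2×
checkerboard contrast); γ = 2; λ = 5 (the amplitude at which a planted loop
is unambiguously a loop); compartment blocks 1–3 Mb; TAD lengths
300 kb–1 Mb tiled *within* compartment blocks, so compartment transitions
coincide with domain boundaries as they overwhelmingly do in real genomes —
an independently placed compartment edge insulates by itself and would be a
planted-but-unlabeled boundary. Loops are placed intra-domain (promoter and
enhancer in one TAD and compartment block), reflecting the canonical
promoter–enhancer geometry; a cross-boundary loop sits on a depressed
background that a domain-aware caller rightly discounts. Query species
derive from the reference by flipping 20 % of compartment blocks, deleting
20 % of (non-edge) boundaries, and gaining/losing loops (20 %/10 %), all
through piecewise-identity homology maps with 2-Mb segments, a 5 % gap rate
and an optional inversion. Gene density is Poisson with a higher rate in A
blocks, which is what orients PC1.

Interaction-level analyses use a dedicated dense fixture — the same depth
concentrated on a 1.5-Mb chromosome with 12 intra-domain loops of
100–300 kb — because 10⁵ contacts on 40 Mb leave < 0.1 counts per 10-kb
pixel, a regime in which no count-based caller can operate (deeply
sequenced, replicate-merged maps are orders of magnitude denser per pixel).

Expression tables are log-normal with per-gene base levels, per-species
effects whose variance scales with a structure-class multiplier, replicate
noise, and planted per-sample scale factors (default 1/2/4 cycling). Motif
fixtures plant one enhancer-TF/promoter-TF pair with high co-occurrence in
HS PEIs on a random-hit background and guarantee the pair a direct PPI edge.

Passing tests on these data show that the estimators recover the structure
they model under Poisson noise at stated depths. They do not exercise:
negative-binomial overdispersion (a dispersion option exists in concept but
the planted thresholds are set under Poisson), restriction-fragment and
mappability bias, translocation-scale rearrangements beyond one inversion,
replicate-level batch effects, or sequence-level realism (no actual motifs
or alignments). Conservation-classification accuracies are reported over
boundaries and PEIs whose anchors lift through the homology maps —
alignment gaps are unclassifiable by construction, in the synthetic maps
exactly as with real liftOver chains.

## Numerical and degenerate-input conventions

Balancing requires a raw matrix and masks zero-marginal bins; O/E strata
with zero expected are set to 0 and flagged on the decay curve; insulation
is undefined within a window of the chromosome ends and where the window is
all-masked; a chromosome lacking low-resolution A or B regions raises
rather than emitting half-defined scores; empty PEI sets, empty states and
sub-minimum gene classes return NA-marked results with warnings rather than
raising. All stochastic steps take explicit seeds; K-means uses a fixed
`random_state` and 10 restarts. Pipeline manifests are JSON with sorted
keys and content hashes, so identical configurations produce byte-identical
manifests.

## Known limitations

Intra-chromosomal analysis only; single-resolution boundary calling (no
multi-scale consensus); no hierarchical/nested TADs; the PEI background is
one multiplicative parameter per domain, not a hierarchical domain
segmentation; promoter-anchor assignment keeps one 10-kb bin per promoter;
the Mann–Whitney enumeration falls back to the normal approximation above
~200 000 assignments; and the evolutionary-state layer substitutes K-means
for a phylogeny-aware state model unless external state calls are supplied.
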