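# Methods

`clonedelim` implements the analytic layer of a multi-locus phylogeographic
survey of a clonal (parthenogenetic) arthropod: haplotype screening,
distance statistics, two species-delimitation criteria (single-threshold
GMYC and Birky's 4x rule), distance-based AMOVA, and strict-clock
divergence dating, together with a coalescent simulator that generates data
with the same statistical structure and known truth.  This note records the
models, the defaults and their rationale, the numerical choices, and what
the synthetic validation does and does not demonstrate.

## Data model

Each locus is an aligned FASTA matrix over `{A,C,G,T,-,N, IUPAC}`.
Haplotype identity is *literal* string equality (gaps and ambiguity codes
compared as characters), matching the counting convention of standard
haplotype-collapsing web tools; an `N` therefore separates haplotypes.  All
group statistics act on a `LineagePartition` (sample -> group), sourced
either from metadata labels or from GMYC entities, so delimitation feeds
the downstream statistics without manual relabelling.

Coding loci carry a genetic-code id (standard or invertebrate
mitochondrial) and a frame offset (default 0; the reading frame of a
fragment cannot be inferred from the alignment and must be configured).
Trailing partial codons are dropped from translation.  Codon-position
masking assigns positions cyclically from the frame offset, so masking
positions 1, 2 and 3 in turn removes disjoint sets covering every column —
a 709-column frame-0 alignment keeps 473 columns after third-position
masking.

## Distances

Uncorrected p-distances use pairwise deletion of gap/`N` sites by default
(per-pair observed distances, as distance tables in this field are usually
reported); complete deletion is available.  Model-based corrections:

- **JC69**: `d = -(3/4) ln(1 - 4p/3)`, undefined at `p >= 0.75` (reported
  as missing with a warning).
- **K2P**: closed form from transition/transversion proportions.
- **GTR+G (+I)**: per-pair maximum-likelihood branch length under a fixed
  GTR model with 4 discrete gamma categories (quantile-midpoint rates),
  found by bounded 1-D optimisation of the pair likelihood on the site
  pattern counts.  Identical sequences are grouped first, so clonal
  alignments with few unique sequences stay cheap.

**Model fitting.**  Base frequencies are empirical counts.
Exchangeabilities (GT fixed at 1) are estimated by composite
independent-pairs maximum likelihood over a deterministic subset of up to
100 unique-sequence pairs, jointly with per-pair branch lengths
(L-BFGS-B, fixed settings, deterministic).  The composite likelihood is an
approximation — pairs share evolutionary history that it ignores — but the
model here only feeds pairwise distance correction, which keeps this module
free of tree inference.

The gamma shape is deliberately *not* estimated by the composite
likelihood.  On data of this shape (a handful of dense clusters separated
by deep stems) the composite profile over the shape parameter is nearly
flat — about 9 log-likelihood units across `alpha in [0.15, inf)` on ~130k
site observations — and its argmax is unstable, erring low often enough to
inflate deep corrected distances by ~75% and wreck dating.  Instead the
shape is estimated from the among-site dispersion of Fitch parsimony
change counts on a JC/UPGMA guide tree: counts are modelled as a
Poisson-gamma (negative binomial) mixture and the moment estimator
`alpha = mean^2 / (var - mean)` is used, clipped to `[0.05, 100]`, with
equi- or under-dispersion mapping to rate homogeneity.  Parsimony
undercounts multiple hits at fast sites, so the estimate is biased mildly
toward homogeneity — the benign direction for distance correction (an
overestimated shape slightly under-corrects; an underestimated one can
diverge).  An invariant-sites proportion can be supplied and is honoured by
the pair likelihood, but the default is 0: on the synthetic data the
zero-count class shows no excess over the negative-binomial expectation.

Nucleotide diversity within a group is the mean pairwise p-distance (`pi`);
the mean raw difference count is reported separately as `d` (a count, not a
proportion).  Group summary tables report the population standard deviation
over pair values.

## GMYC (single threshold)

The chronogram is modelled as a diversification (Yule-type) process that
switches to within-entity coalescence at a threshold age T.  For the
waiting interval i between successive branching events,

    b_i = lam_Y * k_i^p_Y + lam_C * sum_j (n_ij (n_ij - 1))^p_C

with `k_i` the number of species-level lineages (branches crossing the
interval above T; the constant number of entities below it) and `n_ij` the
lineage count of entity j.  The log likelihood is
`sum_i [ln b_i - b_i x_i]` over intervals that end in a branching event;
the final tip-ward interval contributes nothing.  The scaling exponents
`p_Y, p_C` are bounded to `[0, 3]`, the rates to `[e^-18, e^18]`.

Fitting profiles over candidate thresholds at midpoints between
consecutive distinct node ages plus both boundary cases (every tip its own
entity; the whole tree one entity).  Each candidate is optimised from 8
deterministic starts on a fixed lattice over `(log lambda, p in {0.5, 1,
1.5})` with analytic gradients.  The null model `b_i = lam_0 k_i^p_0` is
the boundary candidate with no threshold inside the tree, and its fitted
optimum also seeds that candidate, so `logL_GMYC >= logL_null` holds by
construction.  The LRT uses a chi-square with df = 3 by default (threshold
plus two parameters); df = 2 is printed alongside in reports since the
appropriate df for this non-regular test is debatable.

**Tie handling.**  Tied or zero-separation node ages are perturbed
(parents kept older than children) by `1e-9 * root age` by default.  For
chronograms built from distance data this default is misleading: UPGMA
node heights are quantised at half a substitution (`0.5/L`), and with
nanoscale separation a cluster of one-substitution nodes looks like an
instantaneous branching burst, which the threshold model happily "detects"
(over-splitting five clean lineages into ~15 entities in some replicates).
`branching_intervals`/`fit_gmyc` therefore accept a `min_separation`
parameter; the pipeline passes `0.5/L` for distance-derived trees, which
restores clean recovery (see the acceptance statistics).  User-supplied
chronograms (e.g. from Bayesian dating, which produces continuous heights)
use the default.

Input chronograms must be rooted, binary and ultrametric within a relative
tolerance of 1e-6; non-ultrametric input is rejected with a per-tip depth
report unless smoothing is requested, in which case each node age is
rescaled by the mean depth of the tips below it (adequate for near-clock
trees only).

## Birky's 4x rule

For clades a, b: `theta = pi / (1 - 4 pi / 3)` per clade (the larger of
the two is used), `K` = mean corrected distance over cross pairs, and the
ratio `K/theta` is compared with 4.  The published statements of the rule
overlap at exactly 4, so the implementation reports `> 4` as different
species, `< 4` as same species, and `= 4` (within 1e-9) as an explicit
`boundary` verdict.  The overall species grouping is the connected
components of the same-species relation; non-transitive verdict sets are
merged by that closure and flagged as conflicts rather than resolved
silently.  Sublineage analyses are supported by passing any nested
partition; nothing is detected automatically.

## AMOVA

Two-level (among/within groups) decomposition from a matrix of pairwise
difference counts, used directly as squared distances (the convention of
the standard population-genetics tool for haplotypic data; literal squaring
is available via a flag).  Variance components use the unequal-sample-size
correction; `Fst = Va/(Va+Vb)`; negative `Va` is reported as-is with a
flag.  Significance comes from permuting individuals among groups with
sizes held fixed, `p = (#{Fst* >= Fst} + 1)/(n_perm + 1)`, default 20,000
permutations, seed required for reproducibility.

## Strict-clock dating

UPGMA on corrected distances with deterministic lexicographic tie-breaking
builds the chronogram; node depth is half the merged clusters' mean
distance, i.e. substitutions/site *per lineage*.  `date_nodes` divides
depths by a per-lineage rate, default 0.0115 subs/site/my for arthropod
COI (2.3%/my pairwise).  This is a deliberate, clearly-labelled
replacement for Bayesian MCMC dating: adequate when splits are an order of
magnitude deeper than within-clade diversity (here ~15-18% between vs
<1% within), and not a general-purpose dating method.  The default
correction feeding UPGMA is the fitted GTR+G model; JC69 is the fallback
when model fitting is disabled.

## Synthetic data generator

The generator reproduces the study design the pipeline assumes:

- 5 lineages, splits drawn uniformly in 7.4-11.5 mya on a random join
  order (Yule-style topology);
- one Kingman coalescent per lineage with mean pair coalescence
  `within_ne_my = 0.08` my, chosen so that within-lineage p-distances sit
  around 0.2-0.5% and >= 95% of within-lineage tip pairs coalesce below
  0.5 my (late-Pleistocene population ages), an order of magnitude below
  the shallowest split.  Optional location-level substructure
  (`location_ne_my`) exists for exploration and is off by default;
- the default sampling table has 26 locations / 120 individuals with two
  mixed locations (three lineages in one, two in another), mirroring the
  co-occurrence pattern of the emulated survey; a lineage-pure variant
  supports variance-partitioning experiments;
- three linked loci evolve on the single shared genealogy (clonal
  inheritance, no recombination): COI-like 709 bp at 0.0115 subs/site/my
  (GTR, AT-rich frequencies, weak gamma heterogeneity, codon-position
  multipliers 1 : 0.2 : 5 before normalisation so third positions saturate
  first), H3-like 374 bp at 0.0038 (JC-like), 28S-like 573 bp at 0.0006
  (GTR, GC-rich, strong gamma).  The COI rate and fragment lengths are the
  emulated study's values; the nuclear rates are scaled ~3x and ~20x
  slower so between-lineage distances land near 5-11% and 0.5-1.9%.
  With these settings between-lineage COI p-distances centre on 13.5-18.5%
  — intentionally mid-band, since site-sampling noise at 709 bp (sd ~1.3
  percentage points on a lineage-pair mean) makes edge-hugging defaults
  fail their own calibration in a large fraction of replicates.

Sequences evolve by sampling child states from eigendecomposed transition
matrices branch by branch; site rates are per-site gamma-category draws
times codon multipliers, renormalised to mean exactly 1 so the clock
calibration is exact.  Stop codons in simulated coding loci are tolerated
(sequences are analysed, not expressed).  All randomness flows from one
integer seed through one generator; identical seeds give byte-identical
FASTA output.

**What passing synthetic tests does not show.**  The generator draws clean
alignments (no missing data, no alignment error, no heterogeneity among
locations in sampling depth beyond the fixed table, no recombination, no
selection, no rate variation among lineages).  Recovery statistics on it
validate the *estimators* under the model's assumptions; they say nothing
about robustness to alignment artefacts, numts, or clock violations in
real data.

## Validation problem sizes

The test suite and the acceptance script use: 50 default-design replicates
(120 samples, 3 loci) for recovery statistics; 100 single-population
coalescent trees (n = 40) for the GMYC LRT null rejection rate; brute-force
oracle comparisons at <= 6 sequences/tips at 1e-9; and a two-clade sweep of
split depths for the 4x-rule decision.  The permutation showcase uses the
full 20,000 permutations; replicate loops skip the permutation test, which
is irrelevant to the quantities they measure.

## Known limitations

- Composite-likelihood exchangeability estimates are consistent but not
  efficient; no standard errors are reported for model parameters.
- The parsimony-moment gamma shape is a point estimate with undercount
  bias toward homogeneity; for saturated data beyond ~25% divergence a
  likelihood method on a fixed tree would be preferable.
- UPGMA dating assumes a strict clock and clean, deep splits; it will
  mis-date trees with rate variation among lineages or soft polytomies.
- The GMYC LRT df is conventional, not derived; both df = 3 and df = 2
  p-values are reported.
- AMOVA is two-level only (no hierarchical three-level design, no
  Phi-statistics beyond the Fst analogue).
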