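# Methods

This note records the statistical models implemented in `dupsel`, the
assumptions they make, the numerical choices behind them, and what the
synthetic-data generators do and do not emulate.

## Scope and data model

The package analyses a duplicated gene family sampled across related
species: a codon alignment (optionally with flagged pseudogenes), a gene
tree whose tips carry `<species>_<paralog>` labels, and a partition of
the tips into two paralog clades ("dup1"/"dup2").  Coordinates are
0-based half-open internally; gaps, `N` and IUPAC ambiguity codes are
treated as missing data and masked pairwise by every statistic.  A
terminal stop codon shared by the alignment is stripped before codon
analyses; internal stops either abort (default) or flag the sequence as
a pseudogene, excluding it from model fitting while keeping it in
reports.

## Diversity, neutrality and recombination (popgen)

* **π** is the mean number of pairwise differences over all n(n−1)/2
  pairs, counted on mutually non-missing sites; **θ_W = S/a₁** with
  a₁ = Σ_{i<n} 1/i.  S counts *all* variable sites (multiallelic
  included), matching the Watterson definition; the LD statistics and
  the four-gamete test use biallelic sites only.
* **Tajima's D** uses the 1989 constants (a₁, a₂, b₁, b₂, c₁, c₂, e₁,
  e₂); it is undefined (reported missing, never zero) when S = 0 and
  requires n ≥ 4.
* **Rm** is the Hudson–Kaplan bound: every four-gamete-incompatible site
  pair defines an open interval that must contain a crossover; after
  discarding non-minimal intervals a greedy right-endpoint sweep counts
  the maximum set of disjoint intervals.  This greedy solution is the
  exact minimum (classic interval-scheduling duality); the test suite
  also verifies it against exhaustive search for S ≤ 8.
* **ZnS / Za / ZZ**: r² is the squared Pearson correlation of the 0/1
  allele indicators on haplotypes non-missing at both sites; ZnS
  averages all pairs, Za the S−1 physically adjacent pairs,
  ZZ = Za − ZnS.  Pairs where either site is monomorphic on the shared
  rows are dropped (NaN) rather than scored 0.
* **Hudson's R (per gene)** follows the variance-of-pairwise-differences
  idea: the observed sample variance S_k² of the pairwise difference
  counts is matched to its neutral-coalescent expectation
  E[S_k² | C, n, θ] with θ estimated by π, and C = 4Nc is the solving
  value.  The expectation must account both for the two-locus decay of
  linkage — the pair-of-sites coalescence-time covariance
  (ρ+18)/(ρ²+13ρ+18) — and for the covariances among overlapping
  sequence pairs that deflate the within-sample variance.  Rather than
  an approximate closed form we evaluate the expectation by seeded
  coalescent Monte Carlo (msprime ancestries, binary mutations at rate
  θ/2 per gene) on the per-gene grid C ∈ {0, 0.5, 1, …, 512}, enforce
  monotonicity, and invert by interpolation in log(1+C).  Defaults:
  80 replicates per grid point.  Observed variances above the C = 0
  expectation return the lower bound, below the C → ∞ floor the upper
  bound, both flagged.  The estimator is validated against simulated
  data (median of the estimate within [5, 20] at true ρ = 10, n = 30,
  1000 sites); like all moment estimators of ρ it is noisy at single-gene
  scale and should be read as an order of magnitude.
  R per adjacent site is R_gene / L with L the analysed alignment
  length.

## Coalescent nulls (coalsim)

All null distributions condition on the observed number of segregating
sites: each replicate places exactly S mutations on branches with
probability proportional to branch length, each at a distinct site.
Regimes: `none` — one Kingman genealogy per replicate (direct O(n)
sampler); `free` — an independent genealogy per site, i.e. complete
linkage equilibrium (the convention behind "free recombination" nulls);
`rho` — an ancestral-recombination-graph simulation delegated to
msprime (population size 1, ploidy 1, per-lineage gene-wide
recombination rate ρ/2), with mutations placed on the marginal trees.
Empirical p-values are reported both raw (Pr(sim ≥ obs), which can be 0
or 1) and with the add-one correction (r+1 denominator) so Monte-Carlo
p-values are never exactly 0; confidence intervals are 2.5/97.5
percentiles.  Replicates on which a statistic is undefined are dropped
and counted, with a warning above 10%.  Default 1000 replicates.

## Trees and diversification (phylo)

Distances: p, JC69, K2P (saturated corrections flagged as ∞, never
silently clamped), and the Nei–Gojobori proportions pS ("synonymous
only") and pN ("nonsynonymous only") for codon alignments.  Neighbor
joining is the standard Saitou–Nei Q-criterion algorithm with
lexicographic tie-breaking (deterministic output) and negative branch
estimates clamped to zero with the deficit moved to the sister branch,
preserving the pair's summed length — required for downstream
lineage-through-time validity.

The **γ statistic** uses the internode intervals g_k (duration with k
lineages), T = Σ k·g_k:

    γ = [ (1/(n−2)) Σ_{i=2..n−1} Σ_{k=2..i} k·g_k  −  T/2 ]
        / ( T · sqrt(1/(12(n−2))) )

Under a pure-birth process γ is asymptotically N(0,1); large positive
values indicate a late acceleration of diversification.  Substitution-
scaled NJ trees are not ultrametric, so by default the tree is first
made ultrametric by node-depth averaging (each node's height above the
present becomes the mean of its root-to-tip remainders, children capped
at the parent); the raw-depth variant is available via
`ultrametricize=False`.  Unrooted inputs are midpoint-rooted unless an
outgroup is supplied.  Multifurcations contribute c−1 coincident
events.  The implementation agrees with an independent reference
implementation to 1e-6 on Yule trees, and its null calibration (mean ≈ 0,
SD ≈ 1 over 500 Yule trees of 30 tips) is checked in the acceptance
suite.

## Codon models (codonml)

**Counting.**  NG86 synonymous/nonsynonymous sites are computed per
codon from the three single-nucleotide neighbours at each position;
changes into stop codons are disregarded (the denominator stays 3, so
S + N = 3 per codon).  Multi-step codon differences are averaged over
all minimal mutational pathways, excluding pathways through stops
unless every pathway is blocked.  pS = Sd/S and pN = Nd/N are reported
as proportions (no multiple-hit correction); ω = pN/pS is flagged
infinite when pS = 0 rather than replaced by a sentinel.

**Likelihood.**  A Goldman–Yang-style reversible Markov process on the
61 sense codons: rate 0 for multi-nucleotide changes, π_j for a
synonymous transversion, κπ_j synonymous transition, ωπ_j and ωκπ_j for
the nonsynonymous counterparts.  Codon frequencies default to F3x4
estimated from the data (with a small floor so no sense codon has zero
frequency); simulation defaults to equal frequencies.  One scale factor
is computed from the *background* class mixture so that branch lengths
mean expected substitutions per codon under the background regime;
site classes with ω > 1 therefore genuinely evolve faster, and the
foreground regime of a branch-site model accelerates the foreground
branches.  Likelihoods use Felsenstein pruning over compressed site
patterns with per-node rescaling (no site likelihood underflows to 0),
batched across mixture classes; transition matrices come from the
symmetrized eigendecomposition of the generator.

**Model templates.**  M0, free-ratio (per-branch ω), M1a, M2a, M7/M8/M8a
(beta with K = 10 equal-probability categories at quantile midpoints),
and branch-site model A with classes (ω0, 1, ω0→ω2, 1→ω2) and the
codeml proportion convention p2a = (1−p0−p1)p0/(p0+p1).  Foreground
branches are named by clade tip sets, in two modes: `stem` (the single
branch subtending the clade) and `all` (stem plus every branch inside).

**Fitting.**  Bounded L-BFGS-B on log/logit-transformed parameters.
Branch lengths are optimized jointly under M0 (initialised from the
input tree) and shared by the site-class models; alternative models
start from their fitted null (including a start with the extra
parameter at its boundary, which reproduces the null point exactly), so
the nesting inequalities lnL(M2a) ≥ lnL(M1a), lnL(M8) ≥ lnL(M8a) ≥
lnL(M7) and lnL(bsA) ≥ lnL(bsA-null) hold numerically.  This
shared-branch-length scheme deviates from re-optimising branch lengths
under every class model; it trades a small amount of likelihood for
robustness against the multimodality that extreme foreground-ω
estimates signal, and for speed.  Multi-restart (default 3 total
starts, jittered) guards the class-model parameters.  Non-convergence
is warned, never silent; a negative LRT statistic beyond 1e-3 triggers
an optimizer-failure warning and a NaN p-value.

**Tests.**  LRT p-values come from χ²_df or, for the branch-site test
whose null pins ω2 = 1 at the boundary, from the 50:50 mixture
½χ²₀ + ½χ²₁ (both are available; the mixture is the default for bsA).
Site posteriors are naive empirical Bayes (class posterior ∝ p_c·L_c at
each site), with the positive-selection probability summed over classes
with ω > 1 and a 0.95 flagging threshold; Bayes empirical Bayes is not
implemented and outputs are labelled NEB.  KH and SH topology tests use
RELL: per-topology per-site log-likelihoods (branch lengths, κ and ω
re-optimized per topology under M0), 10 000 multinomial site resamples,
centered pairwise differences for KH (two-sided) and the max-corrected
multiple-topology procedure for SH.

## Codon usage (codonusage)

ENC follows Wright (1990): per-family homozygosity
F̂ = (nΣp² − 1)/(n − 1) averaged within degeneracy classes,
ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, families with fewer than two
observations or non-positive F̂ excluded, a missing F̄₃ imputed as the
mean of F̄₂ and F̄₄, and values clamped at 61.  The neutral expectation
curve is ENC*(s) = 2 + s + 29/(s² + (1−s)²) at GC3 = s.  CBI is
(N_opt − N_ran)/(N_tot − N_ran) over degenerate amino acids; the
optimal-codon set is user-supplied or inferred as the modal codon per
amino acid over the pooled input (ties broken alphabetically, so runs
are reproducible).  Met, Trp and stops are excluded throughout.  Group
comparisons use Welch's t by default (classic equal-variance Student
behind a flag).

## Functional divergence (divergence)

Ancestral reconstruction uses an equal-exchangeability 20-state model
(F81-style) with empirical frequencies — marginal ML at the clade root,
with a parsimony fallback — and per-site substitution counts by Fitch
parsimony.  The radical/conserved partition is fixed and versioned:
charge classes {D,E} / {K,R,H} / rest, hydropathy classes by
Kyte–Doolittle sign (hydrophobic = {A,C,F,I,L,M,V}); a change is
radical iff it crosses either partition.  π_R, the neutral radical
fraction, is the stationary radical share of the replacement model
given the empirical frequencies.

**Type I.**  Per-site counts X₁, X₂ in the two clades.  The model-free
coefficient is θ_I = 1 − ρ̂ where ρ̂ is the rate correlation estimated by
a split-half construction: each clade is cut at the internal edge whose
clade side is closest to half the tips, giving two edge-disjoint
subtrees whose counts carry independent reconstruction noise; the
geometric mean of the four cross-clade subtree correlations divided by
the geometric mean of the two within-clade split-half correlations is
ρ̂.  Because the attenuation calibration is empirical, the estimator
stays centered even though parsimony counts are under-dispersed
relative to Poisson (which breaks the textbook "subtract the mean from
the variance" correction; that Poisson form remains as a fallback for
clades too small to split).  SE by 500-replicate site bootstrap,
z = θ/SE.  The ML coefficient fits the two-state mixture — sites share
one gamma(α) rate across clades with probability 1−θ, or draw
independent rates with probability θ — through the closed-form
negative-binomial marginals, with an LRT against θ = 0 (boundary
mixture p) and an SE from the profile curvature.  Estimates outside
[0,1] are flagged, not clamped.

**Type II.**  Both clade ancestors are reconstructed and every
comparable site classified N (identical), C (conserved change) or R
(radical change); the F00 subset additionally has zero within-clade
changes in both clades.  Type-II divergent sites are property-altering
by definition, so their between-ancestor changes are radical; neutral
changes are radical with probability π_R.  On F00 proportions:

    θ_II = f_R − f_C · π_R/(1 − π_R)

(zero when radical and conserved changes sit in the neutral ratio, one
when every F00 site changed radically).  SE by site bootstrap (default
1000 replicates; z undefined when the ancestors are identical, in which
case θ_II = 0 exactly).  Reported alongside: a_R = R/(R+C) and a_R/π_R,
G_R/G_C = R/C, the all-site N/C/R counts, and F00 proportions.  The
per-site posterior odds of the divergent class use the same model
(divergent sites always radical; neutral no-change probability
calibrated from f_N), with ratio r ⇔ probability r/(1+r), so a ratio of
4 is exactly posterior 0.8.  This estimator is a transparent
moment/likelihood formulation of the cluster-ancestor radical-excess
framework; it is validated by simulation (power and null error rates),
not by matching any particular legacy implementation.

## Synthetic data (synthetic_data)

Every generator is a pure function of (parameters, seed) and emits a
manifest that regenerates its output bit-identically.

* **Trees**: Yule and constant-rate birth-death conditioned on n extant
  tips (forward simulation, extinct lineages pruned, one memoryless
  holding time after the n-th lineage so the internode-interval law is
  exact; the g_k means 1/(kλ) are verified in the tests).
* **Duplication scenarios**: before-speciation (a root duplication with
  two mirrored species clades, stem length 0.15, species-tree depth 0.3
  substitutions/codon by default) and after-speciation (per-species
  paralog cherries).  These depths are typical of a recently radiated
  plant genus sampled at a single nuclear gene.
* **Codon alignments**: exact Gillespie simulation of the 61-state
  process per branch and site class (same generator and scaling
  convention as the likelihood), so realized synonymous/nonsynonymous
  event counts per branch are ground truth, not estimates.
* **Rate-shift data** (type-I exercise): gamma(0.5) site rates, a
  switched fraction redrawing independently in clade 2, Poisson
  substitution counts along resolved Yule clade trees (many short
  branches keep observable counts close to the true Poisson counts).
* **Radical-bias data** (type-II exercise): clade ancestors forced into
  different charge classes at a chosen site fraction, within-clade noise
  at 0.05 replacements/site on star trees.

What the generators do **not** emulate: insertion/deletion evolution,
intron evolution, alignment error, rate variation along branches
(heterotachy beyond the modelled classes), codon-usage selection, gene
conversion between paralogs, and population-level sampling within
species.  Passing the simulation-based checks therefore demonstrates
internal consistency and statistical calibration of the methods under
their own assumptions — not robustness to real-data violations of those
assumptions.

## Validation problem sizes

The acceptance computations run at these sizes, chosen to give stable
Monte-Carlo estimates at single-workstation scale: 1000 random
instances for the Rm oracle (S ≤ 8), 200 random alignments/codon pairs
for the π/LD/NG86 oracles, 2000 fixed-S coalescent replicates for the
Tajima's D and ZZ calibrations, 20 replicates each for M0 recovery
(400 codons), branch-site power (ω2 = 5) and type-I error (300 codons,
6 taxa), 500 Yule trees (n = 30) for γ, 50 replicates for the type-II
power/null rates (255 sites), and 20 replicates of the 500-codon
topology test.

## Known limitations

* Hudson's R inherits the large variance of all moment estimators of ρ;
  single-gene estimates are order-of-magnitude statements.
* The shared-branch-length fitting scheme can understate lnL differences
  relative to full joint optimisation; LRTs remain valid (both models
  see the same branch lengths) but are mildly conservative.
* NEB site posteriors ignore parameter uncertainty (no BEB).
* The type-I ML estimator assumes Poisson counts and is downward-biased
  on parsimony counts from small clades; the split-half model-free
  estimator is the calibrated default.
* The AU topology test and rate-shift (rjMCMC / birth-death SBP) fits of
  LTT curves are out of scope; only KH/SH and γ are provided.
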