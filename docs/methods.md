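# Methods

This note documents the statistical model behind `crispri_screen`, the
assumptions of its synthetic-data generator, and the numerical and design
choices that were genuinely open.

## Fitness from counts

Guide abundance in a sequencing sample is summarized as the
median-centered log2 count, `l = log2(c + 0.5) − median_pool log2(c' + 0.5)`.
The 0.5 pseudo-count keeps zero counts finite; median centering removes
sample-depth and pool-composition scale so that `l` measures abundance
relative to a typical pool member. Centering is exactly
depth-invariant up to the pseudo-count: multiplying all counts by 4
changes `l` by less than 0.1 for counts ≥ 30 (tested).

Uncertainty is attached by resampling: the posterior frequency of a
guide with count `c` in a sample of `C` reads over `N` pool guides is
taken as Gamma(shape `c + 0.5`, rate `C + 0.5·N`) — a Gamma–Poisson
posterior with a flat-ish prior whose mean is ≈ `c/C`. One thousand
frequency draws are converted back to the centered log2 statistic (the
observed pool median held fixed, since only the focal guide is
resampled) and their sample variance is reported. Two remarks:

* Whether the second Gamma argument is a rate or a scale does not affect
  the variance: `var(log X)` for `X ~ Gamma(shape, ·)` is
  `trigamma(shape)`, scale-free. We parameterize with a rate so the
  draws are interpretable as frequencies. The calibration suite checks
  the resampled variance against `trigamma(c + 0.5)/ln²2` and against
  the realized spread of `l` over repeated resequencing simulations
  (agreement within ~15–20 %).
* Holding the median fixed slightly understates the total variance of
  `l`: the realized pool median itself fluctuates between sequencing
  runs (an effect of order 10 % of the per-guide variance at high
  depth). This is intentional — the estimand is abundance relative to
  the realized pool — but it matters when comparing estimates to an
  external truth; see "Recovery benchmark" below.

## Effect contrasts

The induction effect `A` is the difference of fitness with and without
guide induction, `A ~ Normal(l₊ − l₋, s²₊ + s²₋)`; replicates combine by
inverse-variance weighting (`var = 1/Σ(1/var_r)`, mean = weighted mean).
The drug-specific effect `D` contrasts induced growth in a compound with
the induced vehicle (DMSO) control, the control first combined across
its replicates. Both contrasts filter guides with fewer than 30 reads in
the relevant control culture (uninduced for `A`, induced-no-drug for
`D`); for `D` the rule is applied to the mean count across control
replicates, a choice we had to make since the aggregation over replicates
is not otherwise pinned down. Filtered guides propagate as missing
values, never as zeros, so gene-level means are not biased toward null.

Because repression can only produce drug *sensitivity* in this assay,
apparent positive `A` is treated as technical noise when magnitudes are
needed: the **effect magnitude** is `|min(A, 0)|`. Classification
thresholds are strict (`< −1` growth defect on median-centered `A`,
`< −2` effective repression on the gRNA effect), and gene × compound
interactions are flagged when the mean `D` over a gene's unfiltered
guides exceeds 1 in absolute value.

A caveat worth knowing: median-centering is a *relative* measure. If a
large fraction of a pool is depleted in some condition, the pool median
itself moves and unaffected guides acquire a small apparent enrichment
(an order-statistic shift of roughly `σ_pool · Δpercentile`). With one
affected gene among 8–20, as in the reference-set layout, the bias is
well below the |1| interaction threshold; the test suite pins it at
< 0.15 log2 units for a 1-in-10 layout.

## Efficacy determinants

The dCas9 footprint of a guide is its genomic target plus three bases on
each side (26 bp for a 20-nt spacer). Chromatin scores over the
footprint are: mean per-base nucleosome occupancy; mean of the per-base
ATAC insertion signal after a centered 51-bp moving average; or the mean
of the 4-bp tiling-array probes falling in the window (6 or 7 probes).
Position profiles take the median effect magnitude in 50-bp windows
advancing by 25 bp over TSS-relative guide midpoints; correlation
analyses restrict to the TSS −400..+400 window and report Spearman rho
(average ranks for ties, large-sample two-sided P) plus binned medians
(score windows of 0.25, step 0.125, with quartiles).

The sequence-context test works on **relative effects**: each guide's
effect divided by the most negative effect of its drug/gene set, both
clamped to [−6, 0], giving a per-set normalized potency in [0, 1] (sets
with no negative effect map to 0). For each of the 63 sites of the
target region (20-bp flank + 20-nt protospacer + 3-nt PAM + 20-bp
flank) and each base, the median relative effect of carrier guides is
compared to random same-size guide samples; P is the plain fraction of
samples with at least as large a median (a `(r+1)/(n+1)` estimator is
available by flag), Bonferroni-corrected by the 252 tests and capped at
1. TF-site overlap uses the same machinery on mean effect magnitudes at
three overlap levels (site covering the spacer's middle base, its middle
10 bases, or any part), keeping only factors overlapping ≥ 10 guides.

Null statistics are drawn once per distinct subset size within a call
and shared across the tests of that size. Under the global-null
resampling scheme (subsets drawn from the same guide set the observed
subset came from) this is an identical null distribution, and it cuts
the cost of the 252-test table by two orders of magnitude. Permutation
P values are uniform under null simulation (KS-tested in the suite).

## Guide design

TSSs come from transcript-isoform data (modal start, ties toward the
more upstream position) or, absent that, a fixed 27 bp upstream of the
ATG on the coding strand. Guide enumeration scans both genomic strands
for NGG PAMs and emits every protospacer whose midpoint falls in the
requested TSS-relative window; midpoint membership also decides
boundary-overlapping guides. The strand class records which gene strand
the gRNA base-pairs with (a protospacer on the coding strand means the
guide anneals to the template strand). The mismatch series substitutes
one random alternative base at each seed position 1–10 and at 11, 12,
14, 16 (PAM-proximal numbering), each derivative emitted in 20-nt and
truncated 18-nt form.

Ranking encodes the empirical design rule: tier 1 = midpoint within
200 bp upstream of the TSS *and* footprint occupancy below the local
median (TSS ± 500 bp; the threshold quantile is configurable since the
depletion cutoff is not quantified anywhere authoritative), tier 2 =
in-window only, tier 3 = depleted only, tier 4 = neither; guides without
track coverage rank last. Ties break toward lower occupancy, then
smaller TSS distance. A small tolerance (1e-9) guards the
depleted-vs-threshold comparison against float averaging noise.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis relies
on, not yeast biology per se:

* **Locus**: genes on alternating strands, 2 kb apart; each promoter has
  a nucleosome-depleted region (occupancy 0.05 by default) from −250 to
  −10 of the TSS and cosine-phased nucleosomes (165-bp period) elsewhere;
  the ATAC track is `10·(1 − occupancy)` plus noise (sd 5 % of scale).
  PAM dinucleotides are guaranteed in every 50-bp window so tiling never
  starves.
* **Potency**: a logistic in (TSS-relative position, footprint
  occupancy) with a guide-intrinsic Normal(0, 1.6) logit term standing
  in for untracked determinants (sequence context, RNA structure).
  Constants (weights 0.5/0.5, offset 0.62, steepness 4, position bump
  centered −100 bp with 150-bp scale) were calibrated once so that with
  the default locus ~40 % of guides in a ±500 bp window are effective
  while roughly three quarters of in-window, depleted (tier-1) guides
  are — the regime screens of this design report.
* **Growth**: deterministic exponential change. Induced samples multiply
  a guide's abundance by `2^(T·s·potency)` with `T = 20` pool doublings
  and `s` the gene × compound selection coefficient per doubling
  (default reference set: diagonal `s = −0.2`, i.e. `T·s = −4` at full
  potency). Uninduced samples have `s ≡ 0` (the repressor sees no guide).
  Stochasticity enters only through lognormal initial abundances
  (σ = 0.5, a free dispersion parameter — transformation bottlenecks are
  not independently known) and multinomial sequencing at the configured
  depth. No birth–death noise, PCR jackpots or chimeras are modeled, so
  replicate spread on synthetic data reflects sequencing only and is
  narrower than biological replicates would be.
* **Reads**: exact per-cell read emission (constant scaffold + dual
  sample barcodes + spacer), optional 1-nt spacer corruption of a chosen
  fraction of reads to exercise perfect-match rejection. Base qualities
  are constant; no quality-dependent errors.

One global seed fans out to per-stage child seeds (locus, potency,
counts, reads), so identical configurations are bit-identical and stages
are independently reproducible.

Consequently, passing benchmarks demonstrate the *pipeline's*
correctness and calibration under its own assumptions — they do not
certify potency predictions on real chromatin, nor error rates under
real sequencing artifacts.

## Benchmarks and problem sizes

The validation suite (`crispri_screen.benchmarks`) uses these problem
sizes, chosen to make each check statistically meaningful at desk scale:
round trip 4 genes × 8 guides × 10 samples at depth 2·10⁴; recovery 30
genes × 10 guides at depth 10⁶ with 2 replicates and a sparse truth (6
drug-sensitive genes); variance calibration counts {30, 100, 1000} at
1000 draws; interaction specificity 20 seeds of an 8-gene diagonal
screen at depth 2·10⁵; permutation-null calibration 500 replicates at
1000 permutations; design enrichment 10 seeds of 5 genes × 60 guides.

The recovery benchmark compares **median-centered** A estimates with
median-centered truth. The raw comparison against `T·s·potency` is
confounded by the realized-pool-median noise discussed above — a shared
~0.01–0.03 log2 shift that the reported variances rightly exclude but
which dominates per-guide uncertainty at depth 10⁶. Median-centering
the estimates (the same step applied before any interpretation of A)
cancels the shared term and makes the coverage statement a test of
per-guide calibration, which is the quantity of interest.

## Known limitations

* The Gamma-resampling variance ignores pool-median fluctuation across
  sequencing runs (by construction; ~10 % at high depth).
* Interaction calling is an effect-size flag, not an error-controlled
  test; no P values or FDR are attached to gene × compound cells.
* The permutation tests share null draws within a call (valid, but the
  P values of same-size tests are correlated across rows of one table).
* RNA secondary structure and melting temperature are accepted only as
  user-supplied per-guide covariates; no folding is computed.
* 18-nt spacers whose 20-nt extension collides with another guide are
  counted under longest-match priority and flagged at library load.
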