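# Methods

`clinesel` re-creates, on synthetic data, the chain of evidence by which a
missense variant in a transcription-factor gene can be argued to (i) sit on
a latitudinal allele-frequency cline beyond what shared ancestry explains,
(ii) carry the haplotype footprint of recent positive selection in a
founder population, and (iii) exert *trans* effects on adipocyte gene
expression in risk-allele carriers.  Every statistic is implemented in the
package; the generators below define the study conditions under which the
tests and the acceptance script exercise them.

## Synthetic data generators

### Wright–Fisher haplotype panels

Forward, discrete-generation Wright–Fisher reproduction of phased
haplotypes (2N rows × L sites).  Parents are drawn with probabilities
proportional to fitness 1 + s·(derived dosage at the focal site); each
gamete recombines with a Poisson number of crossovers (rate = per-bp
recombination rate × region length), positions uniform on the genetic map,
which is uniform cM/Mb by default.  Population splits copy the parent pool
through one round of Wright–Fisher sampling; an optional island model
exchanges a fixed fraction of gametes per generation.  Founding haplotypes
are drawn at linkage equilibrium with per-site derived frequencies uniform
in (0.05, 0.95) unless specified; linkage disequilibrium therefore reflects
only the simulated pedigree, so the *pedigree depth* (number of generations
run, capped in effect by 2N) controls haplotype-tract lengths.  Two
deliberate stylizations:

* `focal_single_origin` plants all initial derived copies of the focal
  allele on one founder background — a variant that arose once — which is
  the regime in which extended-haplotype statistics are meaningful;
* `sweep_start_generation` lets a neutral burn-in precede selection, so a
  recent partial sweep sits on top of older neutral coalescent structure.

Counts per site stay in {0..2N}; with zero recombination every offspring
haplotype equals a parental haplotype; identical seeds give identical
panels (all asserted in tests).

The simulator is calibrated against closed forms rather than against any
external tool: neutral focal-frequency drift stays within binomial bounds,
selection raises the mean trajectory, and after a clean split the
multi-site (ratio-of-sums) Weir–Cockerham F_ST tracks 1 − exp(−t/2N) to
within 20%.  Note that the *mean of per-site* F_ST ratios is biased
downward relative to this expectation (Jensen's inequality on a ratio);
the package therefore exposes `weighted_fst` (sum of *a* components over
sum of *a+b+c*) for multi-site summaries, matching the convention of the
standard command-line tool.

### Allele-frequency clines

Per-population derived-allele frequencies are generated on the logit
scale: logit(p) = intercept + slope·latitude + b, with b a Brownian-motion
draw on the population tree (covariance = σ²·shared root-to-tip branch
length).  The logistic link keeps frequencies strictly inside (0, 1).
Mean annual temperature, when not supplied, is a lapse-rate surrogate
(25 − 0.45·|latitude| °C plus noise) so that latitude and temperature are
strongly collinear — as they are in real population panels, which is what
makes the multi-model comparison interesting.  Default study conditions:
22 populations, latitudes 0–65°, slope 0.08 logit/degree, σ² = 0.1.

### Single-nucleus expression cohorts

Donor genotypes at the risk variant follow Hardy–Weinberg at the risk
allele frequency (default 0.3); carriers have ≥1 risk allele.  Counts are
negative-binomial (Gamma–Poisson, dispersion θ = 2) with lognormal
gene-specific means, a lognormal per-donor scaling (SD 0.1 on the log
scale) that induces the within-donor correlation making donor-level
permutation necessary, and multiplicative shifts for planted cell-type
markers and for the trans gene set in carrier donors' adipocytes.  Empty
droplets (all-zero nuclei) are removed, as nucleus QC would.  Degenerate
genotype draws (all carriers or none) are retried up to a bound, then
rejected.  Default trans conditions mirror the discovery/replication
design: 60 donors × 200 nuclei, 12 trans genes, 2-fold shift.

### Twin cohorts

BMI-discordant pairs, one higher- and one lower-BMI member each, with
lognormal TPM-like expression.  A Gaussian copula ties the designated gene
to adipocyte diameter at a target Spearman ρ via the identity
ρ_S = (6/π)·asin(r/2); correlations can be planted in one BMI group only.
Default: 44 pairs, ρ = 0.55, diameters ~85 ± 12 µm.

What the generators do **not** emulate: mutation (sites are pre-seeded),
realistic site-frequency spectra, Finnish demographic history, ambient RNA
or doublets, and gene-length/GC effects on counts.  Green tests therefore
certify the statistics and their wiring, not performance on real cohorts.

## Selection statistics

EHH for a core allele is the probability that two random carrier
chromosomes are identical from the core out to a site, computed by exact
partition refinement (numba-accelerated, with a pure-numpy fallback and an
exhaustive pairwise oracle in the tests).  Curves start at 1 and are
non-increasing; decay distance is measured to the most distant site with
EHH ≥ threshold, flagged as censored at the panel edge.  iHH integrates
EHH over genetic distance (trapezoid, both directions, truncated at the
last site ≥ 0.05 with no interpolation past it); iHS = ln(iHH_A/iHH_D),
negative for long derived haplotypes, standardized within equal-width
derived-frequency bins ((x − bin mean)/bin sample SD), and ranked by
magnitude against a background (strict-less-than, denominator = background
size).  Defaults: MAF ≥ 0.05, 50 bins over [0.05, 0.95], no gap penalty
(physical gaps > 200 kb are flagged on curves).

Scaled-down selection study: 300 diploids, 3,000 sites at 1 kb spacing,
2 cM/Mb, 600 neutral generations then a 50-generation sweep of a
single-origin allele from frequency 0.05 at s = 0.05, retried (bounded,
seed-offset) until the focal frequency lands in [0.35, 0.85] because iHS
is undefined near loss or fixation.  The focal value is standardized in
8 bins against ~9,000 pooled records from six neutral replicate panels —
the scaled analogue of a chromosome-wide background.  At these shallow
pedigree depths the EHH *floor* (the chance that two chromosomes coalesce
recently enough to be identical panel-wide) sits well above the 0.05 used
on deep real panels, so decay-distance comparisons between the focal
alleles use a 0.25 threshold; the statistic's definition is unchanged.
Under these conditions the swept allele's standardized iHS averages about
−2.5 and exceeds the 90th background percentile in ~90% of trials.

## F_ST and the matched empirical null

Per-site Weir–Cockerham (1984) θ̂ = a/(a+b+c) from individual-level
variance components; negative raw estimates are clipped to 0 for reporting
with the raw value retained.  The empirical null for a focal site ranks
candidates by |candidate frequency − focal frequency| (ties broken by site
order, making selection deterministic), takes the closest k (default
10,000, truncated to availability), and reports the proportion with F_ST
*strictly* greater than the focal value; an add-one variant is emitted
alongside because a proportion of exactly zero is otherwise possible.
LD is phased-haplotype r², windowed ±1 Mb with a per-population MAF > 0.05
filter, compared between populations by a two-sided Wilcoxon rank-sum.

## PGLS cline modelling

Neighbor joining (Saitou–Nei Q-criterion; negative pendant branches
clamped to zero with the deficit moved to the sister so path lengths are
preserved) supplies the tree; midpoint rooting defines the Brownian-motion
covariance (shared root-to-tip branch length).  GLS estimates
β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y with the Brownian rate σ² profiled at its ML value;
AIC counts the variance as a parameter.  The response is the raw frequency
by default with a logit option; parameter-recovery runs use the logit
scale, matching the generator.  Pagel's λ is fixed at 1 (no transformation
family), residual normality is reported via Shapiro–Wilk on the whitened
residuals.

For the nested model comparison, the LR statistic 2Δlogℓ is reported with
two p values.  Because V is fixed by the tree, the whitened models are
ordinary Gaussian regressions and the LR statistic is a monotone function
of the exact F statistic; the default p uses the F(df, n − p_full)
reference, which is calibrated at n = 22 where the asymptotic chi-square
is measurably anticonservative (≈0.066 empirical size at nominal 0.05 in
2,000-replicate null simulations; the F reference sits at ≈0.045).  The
chi-square p is reported alongside as `p_chi2`.  Akaike weights
w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2) are computed over {null, latitude,
temperature, full}; predictor weights sum the weights of models containing
the predictor.  Leave-one-out refits drop one population and its tip at a
time and report the slope envelope.

## Trans-expression analyses

Normalization is ln(1 + 10,000·count/cell total).  Marker tests are
one-vs-rest Wilcoxon rank-sum on normalized values for genes passing a
log2 fold-change pre-filter (0.25, positive-only), with fold change
defined as log2((mean expm1 + 1)in/(mean expm1 + 1)out) — the pinned
convention, since toolkit versions differ on the base.  Bonferroni uses
the number of genes tested in the run at hand (markers: per type;
risk-allele tests: the supplied gene set; replication: the genes carried
forward), never a genome-wide denominator.  Unique markers subtract the
union of all other types' marker sets.  Replication requires adjusted
p < 0.05 *and* a concordant fold-change sign.  Rank-sum tests use the
exact null when both groups have ≤25 tie-free observations, otherwise the
normal approximation with tie and continuity corrections.

Module scores bin all genes into 24 equal-frequency bins of mean
normalized expression and draw 100 control genes per gene-set member from
the member's bin (seeded; without replacement when the bin allows, with
replacement and a warning otherwise); the score is the mean over the gene
set minus the mean over the pooled unique controls.  The group comparison
is a two-sided rank-sum on cell-level scores.  Its permutation null
shuffles carrier labels at the **donor** level — cells keep their donor,
preserving within-donor correlation — using per-donor rank sums so each
permutation costs O(#donors); the fast path is asserted equal to the
library rank-sum p in tests.  The permutation p is (r + 1)/(B + 1) by
default with the raw proportion r/B alongside; when donors admit fewer
than B distinct assignments, all are enumerated.  Sex-stratified runs
repeat the risk-allele test within each sex, skipping a sex whose donors
fall in one carrier group, and report significance tiers at adjusted
p < 0.05/0.01/0.001/0.0001.

## Pseudobulk correlation analyses

Pseudobulk sums nuclei counts per donor within a cell type (donors with
zero such nuclei dropped and listed; nuclei counts kept as a covariate).
TMM follows the canonical recipe: reference = sample whose 75th-percentile
count fraction is closest to the mean; per-sample factors from
precision-weighted mean log2 ratios doubly trimmed (30% on M, 5% on A);
factors rescaled to geometric mean 1 (asserted to 1e-12); factors agree
with the Bioconductor implementation within 5% on spiked asymmetric-DE
matrices (tested via Rscript).  Covariate adjustment regresses each gene
on nuclei count, age and sex (OLS with intercept) and applies a rank-based
inverse normal transform with the Blom offset (rank − 3/8)/(n + 1/4), ties
averaged — adjustment before transform, in that order.  Regional analyses
take all genes whose bodies overlap [anchor TSS − 1 Mb, anchor TES + 1 Mb]
(1-based inclusive coordinates) and report pairwise Spearman ρ with
two-sided p, flagging pairs above nominal 0.05.  Size correlations
inverse-normal transform diameters within each BMI group, correlate per
gene per group, and Bonferroni-correct over all gene×group tests in the
invocation.

## Problem sizes and numerical choices

Simulation sizes used by the test suite and acceptance script (all chosen
as the package's standing study conditions): neutral calibration panel
100 diploids × 12,000 sites × 300 generations; sweep trials as above
(20 trials in the test suite, 12 in the acceptance script); 500 cline
replicates for slope recovery and 2,000 for test size; trans cohorts
60 donors × 200 nuclei × 100 genes over 20 seeds; 10,000 permutations for
the module-score null.  Covariance matrices receive a jitter of
1e-10·trace/n before Cholesky; NJ tie-breaks take the first Q minimum in
row-major order; empirical-p tie-breaks follow site order.  Degenerate
inputs (monomorphic sites, zero-total cells, all-zero donors, <2 carriers
of a core allele) are rejected or emitted as missing exactly as the
operation contracts state.

## Known limitations

Cell-level rank-sum tests on pooled nuclei are anti-conservative under
donor correlation — the donor-level permutation test is the guard, and a
pseudobulk sensitivity route exists through the adipose module.  The
forward simulator's linkage-equilibrium founding underestimates deep
coalescent structure, which is why scaled thresholds (EHH floor, bin
count) differ from those sensible on real panels.  NJ on noisy distance
estimates can produce zero-length branches whose covariance is singular up
to jitter.  None of the synthetic calibrations certify behavior on real
genotype or expression data.
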