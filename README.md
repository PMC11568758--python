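# clinesel

Analysis pipeline for a question that spans population genetics and adipose
single-nucleus transcriptomics: **is a derived risk allele distributed along
a latitudinal cline, selected for in a founder population, and connected to
trans effects on adipocyte gene expression?**  The package implements the
full chain of statistics — Weir–Cockerham F_ST with frequency-matched
empirical nulls, extended-haplotype statistics (EHH, iHH, iHS), neighbor
joining and phylogenetic generalized least squares (PGLS), single-nucleus
marker/differential-expression/module-score analyses with donor-level
permutation, and pseudobulk TMM + inverse-normal correlation analyses —
and exercises them end to end on seeded synthetic cohorts, since the real
cohorts such a study uses are controlled-access.

## The statistics at the core

* **EHH / iHS.** For chromosomes carrying one allele at a core SNP, EHH(x)
  is the probability that two random carriers are identical from the core
  out to x; it starts at 1 and decays with distance.  iHH integrates EHH
  over genetic distance per allele, and iHS = ln(iHH_A / iHH_D):
  strongly negative values mean unusually long derived-allele haplotypes,
  the footprint of recent positive selection.  iHS is standardized within
  derived-allele-frequency bins and ranked by magnitude against a
  background scan.
* **F_ST with a matched null.** Per-site Weir–Cockerham θ̂ = a/(a+b+c)
  between two populations; the focal site's value is ranked against the k
  sites with the closest allele frequencies, p = proportion strictly
  greater.
* **PGLS.** Allele frequency regressed on latitude and mean annual
  temperature with Brownian-motion covariance from a population tree
  (Σ_ij = shared root-to-tip branch length), σ² profiled by ML; nested
  models compared by likelihood ratio (exact-F reference; chi-square
  alongside) and Akaike weights; stability probed by leave-one-out.
* **Trans expression.** Seurat-convention log-normalization, one-vs-rest
  Wilcoxon markers (log2 FC ≥ 0.25, Bonferroni over genes tested), unique
  markers by set difference, carrier vs non-carrier tests with replication
  requiring concordant direction, module scores against expression-matched
  control genes, and a donor-level permutation null for the module-score
  comparison.
* **Pseudobulk correlations.** Per-donor sums → TMM factors → covariate
  adjustment → Blom inverse-normal transform → regional (±1 Mb) gene–gene
  Spearman correlations, plus expression-vs-adipocyte-diameter Spearman
  correlations within BMI-discordant twin groups.

## Worked example

The numbered scripts under `analysis/` run each arm on synthetic data and
write tables under `results/`:

```bash
python analysis/02_selection_scan.py
```

```
12 sweep trials (s = 0.05, partial sweep):
  mean standardized iHS          -2.74 (negative = derived-allele selection)
  >90th percentile & negative    100%
  derived EHH decays farther     100%
  mean extra derived decay       1652 kb
neutral calibration (1691 SNPs): mean 0.011, SD 0.989, |iHS|>=2 fraction 0.031
```

Each trial sweeps a single-origin derived allele (s = 0.05) over the last
50 of 650 generations and ranks its standardized iHS against a pooled
neutral background: the swept allele lands around iHS ≈ −2.7 — negative,
i.e. the *derived* haplotype is the long one — and above the 90th
percentile of the neutral scan, while a fully neutral scan is calibrated
(mean ≈ 0, SD ≈ 1, ~5% of sites beyond |iHS| ≥ 2).

```bash
python analysis/03_fst_cline_pgls.py
```

```
focal F_ST 0.4875; empirical p 0.3340 against 1000 frequency-matched sites

PGLS on the logit frequency of 22 populations:
  null         AIC   101.97  logL   -48.98
  latitude     AIC    -1.10  logL     3.55
  temperature  AIC    28.66  logL   -11.33
  full         AIC    -0.31  logL     4.15
  latitude slope 0.0907 (LRT p 1.17e-20, df 2)
  Akaike predictor weights: latitude 1.000, temperature 0.403
  leave-one-out latitude slope range [0.0832, 0.0945]
```

The generator planted a latitude slope of 0.08 logit/degree on this tree;
PGLS recovers it (0.091, leave-one-out envelope [0.083, 0.094]), latitude
carries essentially all the Akaike weight, and the ancestry-only null is
rejected.  A drifting (unselected) focal SNP, by contrast, is unremarkable
against its frequency-matched F_ST null (p = 0.33).

```bash
python analysis/04_trans_expression.py
```

```
unique adipocyte markers: ['g0100', 'g0101']
risk-allele DE: 12/12 genes Bonferroni-significant in discovery; 12 replicated with concordant direction
module-score group test p = 0.00e+00; donor-permutation p = 1.00e-04 (raw proportion 0.00e+00, B = 10000)
sex F: 12/12 significant (tiers [4, 4, 4, 4, 4, 4, 4, 4, 4, 4, 4, 4])
sex M: 0/12 significant (tiers [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0])
```

The planted 12-gene trans module (2-fold in carriers, 60 donors × 200
nuclei) is fully discovered and replicated; in 10,000 donor-level
permutations no relabelling matches the observed module-score separation
(p = 1/10,001); and a female-only planted effect is detected only in
females.

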