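# stratclust

Population-stratification-aware molecular reclassification of affected
individuals from candidate SNP panels.

## The problem

Clustering patients on disease-associated SNP genotypes is an appealing way
to look for molecularly defined disease subgroups (for example in Crohn's
disease, where over a hundred susceptibility loci are known but clinical
subphenotypes map poorly onto them). Allele frequencies, however, differ
systematically between ancestral populations, and some disease-associated
variants are unusually differentiated between continents. A cluster analysis
run directly on genotypes therefore tends to rediscover *population strata*
rather than disease biology: a cohort with even a small minority of
non-European patients can yield a "patient subgroup" that is really an
ancestry group.

`stratclust` implements the full workflow for detecting and removing this
confound when only a candidate-marker panel (no genome-wide data) is
available:

1. **Ancestry assignment** — cluster the cohort together with a labelled
   reference panel on a small set of ancestry informative markers (AIMs)
   using PAM with Euclidean distance; each individual inherits the majority
   population of its cluster, with a silhouette width measuring how firmly
   it sits there.
2. **Ancestry PCs** — standardise the AIM genotypes
   (`s_ij = (g_ij − 2p_j)/√(2p_j(1−p_j))`, missing → 0) and take the top
   sample-space principal components `A` (n × k).
3. **Adjustment** — project the disease-SNP matrix onto the orthogonal
   complement of the PC span,

   `G′ = (I − A(AᵀA)⁻¹Aᵀ) G`,

   computed column-wise on the observed entries only (missing genotypes stay
   missing in `G′`).
4. **Clustering** — on both the unadjusted and the adjusted matrix:
   binomial latent class analysis (EM, missing-at-random, class number by
   parametric-bootstrap LR testing or BIC, per-SNP Wald Z-scores), PAM with
   average-silhouette selection of k, and Ward agglomeration on squared
   Euclidean distances with k chosen from the percent change of the
   agglomeration criterion. Pairwise distances with missing genotypes are
   scaled up proportionally to the number of markers actually shared.
5. **Association battery** — Fisher's exact test (enumeration or
   Monte-Carlo), Pearson chi-squared with margin-preserving resampling, and
   the Hubert–Arabie adjusted Rand index between partitions.

A Balding–Nichols simulator (`stratclust.simdata`) generates study-shaped
cohorts — three continental populations with strongly unbalanced sizes, a
high-F<sub>ST</sub> AIM panel, a low-F<sub>ST</sub> disease panel optionally
containing highly differentiated SNPs, latent disease subgroups with
subgroup-linked categorical subphenotypes, and per-SNP missingness — so the
whole pipeline can be validated against known ground truth.

## Worked example

The package bundles the class-by-population contingency table of a published
845-patient Crohn's disease cohort in which one latent class of 17 patients
was dominated by individuals of African ancestry. The headline association
test is reproduced exactly:

```bash
$ stratclust demo-published-test
X2 = 409.14, resampled p = 0.00001 (B = 99999), asymptotic p = 1.05e-62
```

The resampled p-value is `(1 + #{X²_sim ≥ X²_obs})/(B + 1)` with both table
margins fixed; 0.00001 is the smallest value attainable with B = 99999 —
i.e. no resampled table ever matched the observed association.

Running both analysis arms on a simulated study-shaped cohort
(430/17/3 Europeans / Sub-Saharan Africans / East Asians, 30 AIMs,
51 disease SNPs):

```python
from stratclust import PipelineConfig, SimConfig, run_pipeline

report = run_pipeline(PipelineConfig(seed=7, sim=SimConfig(),
                                     methods=("pam", "ward"), assoc_B=9999))
for name, t in report.population_tests.items():
    print(f"{name}: X2={t.statistic:.1f}, p={t.p_value:.4f}")
```

```
pam_unadjusted: X2=5.2, p=0.0550
ward_unadjusted: X2=29.0, p=0.0006
pam_adjusted: X2=2.7, p=0.2838
ward_adjusted: X2=4.5, p=0.3227
```

Before adjustment the Ward partition is strongly associated with population
(p = 0.0006); after projecting out two ancestry PCs the association is gone
in both methods. The report also carries the per-method selection traces,
population-by-cluster tables, subphenotype scans and the pairwise ARI
matrix of all partitions.

## Limitations

With only ~30 ancestry markers the principal components are noisy estimates
of ancestry, and regression on noisy covariates under-corrects: simulated
cohorts show that a minority of replicates retain a significant
population-cluster association even after 2-PC adjustment (see
`docs/methods.md` for the analysis). The simulator draws markers
independently (no linkage disequilibrium) and uses MCAR missingness.
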