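# onsetmod

Kinship-aware modifier-gene analysis of Alzheimer's disease age of
onset (ADAOO) in founder pedigrees.

## The problem

In the Colombian "Paisa" founder pedigree, every carrier of the fully
penetrant *PSEN1* E280A mutation develops Alzheimer's disease — but
onset ranges from the early 30s to the late 70s. The scientific
question is not *whether* carriers get sick but *when*, and which
**modifier variants** shift that age. Answering it on a candidate SNP
panel requires statistics that respect the data's two awkward
features: everyone in the sample is related (a founder population with
heavy endogamy), and the sample is small (tens of carriers), so naive
regression p-values are anticonservative and cell counts for
interaction analyses are tiny.

`onsetmod` is a reusable pipeline for exactly this design: genotype
QC, kinship-corrected single- and multi-locus association under three
genetic codings, multiple-testing correction, two-locus epistasis with
resampling inference, and mixture decomposition of the onset
distribution — plus a synthetic-cohort generator that reproduces the
statistical structure of such a study (pedigree kinship, a
candidate panel, onset mean ~48.8 ± 4.9 years, a handful of
onset-delaying variants) for testing, calibration and power analysis.
It is aimed at statistical geneticists working with familial
quantitative traits in isolate populations.

## The model

The quantitative trait y (onset age in years) is modeled with a linear
mixed model per marker:

    y = Xb + g·beta + u + e,   u ~ N(0, sigma_g^2 K),   e ~ N(0, sigma_e^2 I)

where X holds sex and years of education, g is the genotype coded
additively ({0,1,2}), dominantly ({0,1,1}) or recessively ({0,0,1}) on
minor-allele dosage, and K is the pairwise relatedness matrix (a
genotype-based GRM, or the pedigree additive-relationship matrix).
Fitting is REML via a single spectral decomposition of K, profiling
the ratio delta = sigma_e^2/sigma_g^2. Wald t-tests use a
Kenward–Roger-type covariance adjustment with Satterthwaite degrees of
freedom, which keeps the scan's type-I error at its nominal 5% even at
n ≈ 80–100 under strong relatedness. Scans are corrected by
Benjamini–Hochberg FDR and by an extreme-value (GEV) fit to
permutation maxima; multi-locus models are built by forward/backward
stepwise search (≤ 10 steps) under an extended-BIC criterion, with the
variance explained by each selected marker accounted sequentially.
Marker pairs are screened with a full two-locus decomposition
(additive/dominance/aa, ad, da, dd terms) of covariate-adjusted
genotype-cell means, with percentile-bootstrap confidence intervals
and label-permutation p-values (add-one estimator, B = 10,000 by
default).

## Worked example

```python
import onsetmod as om

cfg = om.default_emulation_config(seed=7)      # n=78 carriers, 65 SNPs
cohort = om.simulate_cohort(cfg)

panel, qc = om.apply_qc(cohort.genotypes)
scan = om.single_locus_scan(panel, cohort.phenotypes,
                            cohort.kinship_true, coding="dominant")
model = om.multilocus_select(panel, cohort.phenotypes,
                             cohort.kinship_true, coding="dominant")
fit = om.fit_mixture(cohort.phenotypes.adaoo.to_numpy(), k=2, seed=7)
```

printed (seed 7):

```
cohort: n=78, markers=65
onset age: mean=47.9 y, sd=5.0 y
QC: 65/65 markers pass (HWE alpha=0.00077)
  snp  beta   se        p    p_fdr
 snp1  11.4 1.99 2.02e-07 1.31e-05
 snp2  4.47  1.3 0.000985    0.032
snp64 -2.81 1.08   0.0108    0.235
multi-locus model: ['snp1', 'snp2']
per-marker PVE: {'snp1': 0.351, 'snp2': 0.229}
total variance explained: 57.9%
onset mixture: means=[47.3 60.6], weights=[0.95 0.05]
```

Reading it: the generator planted three onset-delaying variants
(+8.21 y dominant at MAF 0.046, +3.68 y dominant at 0.396, +3.27 y
recessive at 0.339). At n = 78 the scan finds the two dominant ones
(`snp1`, `snp2`); their joint fixed effects explain ~58% of the onset
variance in this draw (the recessive variant, with ~9 expected
minor-allele homozygotes, is usually below the selection criterion at
this sample size — exactly the small-sample behavior the package is
built to quantify). Estimates are noisy at this n: `snp1`'s beta of
11.4 ± 2.0 covers the planted 8.21.

The same stages run from the shell:

```
onsetmod run --seed 7 --out run7/          # simulate -> QC -> scan -> ... -> report
onsetmod qc --geno geno.vcf --min-cr 0.90 --min-maf 0.01
onsetmod scan --geno geno.vcf --pheno phen.tsv --coding dominant
```

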