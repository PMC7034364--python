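# slegrs

Cumulative genetic-risk analysis for systemic lupus erythematosus (SLE)
case/control cohorts: polygenic score construction, disease enrichment,
subphenotype association, screening predictive values, and age-scale
survival comparison across score strata.

## The problem and who this is for

SLE susceptibility is polygenic: dozens of common variants each shift
risk modestly, and their cumulative burden predicts not only who
develops the disease but how severe it becomes — earlier onset, more
organ damage, renal failure, worse survival. This package implements
that analysis chain for genetic epidemiologists working with a
case/control cohort genotyped on a risk-SNP panel, and ships a
synthetic-cohort generator so every stage can be exercised and tested
without patient data.

## The scores and statistics

For individual *i* with risk-allele dosages *g<sub>ij</sub>* ∈ {0, 1, 2}
over a panel of *m* biallelic SNPs with per-SNP susceptibility odds
ratios OR<sub>j</sub>:

- **GRS** (weighted genetic risk score):
  GRS<sub>i</sub> = Σ<sub>j</sub> ln(OR<sub>j</sub>) · g<sub>ij</sub>
- **RAC** (risk allele count): RAC<sub>i</sub> = Σ<sub>j</sub> g<sub>ij</sub>

Per-SNP odds ratios are the allelic ORs from the case/control 2×2
allele-count table (Haldane–Anscombe +0.5 when a cell is empty), so
weights can be re-estimated from the cohort itself. Around the scores:

- rank-based quartiles (combined cohort for enrichment; cases only for
  subphenotype and survival contrasts) and fixed-size score bins;
- logistic and proportional-odds ordinal regression (Wald inference),
  with age — and optionally age at diagnosis — as covariates;
- AUC by the Mann–Whitney identity, the DeLong paired test for
  GRS-vs-RAC discrimination, and onset-age-stratified AUC;
- screening PPV/NPV at an assumed population prevalence, in a forward
  (empirical 2×2 at a cut-off) and an inverse (solve sensitivity from
  specificity + positive rate) mode;
- Kaplan–Meier curves, the Gehan–Breslow generalized Wilcoxon test
  (permutation variance; exact enumeration for small samples) and Cox
  proportional-hazards ratios with Efron ties, on the age scale.

## Worked example

Simulate a cohort of 3803 individuals (~1000 cases) and analyse it end
to end:

```sh
slegrs full --seed 11 --out demo
```

This writes `scores.csv`, `associations.csv`, `survival.csv`,
`binned_prevalence.csv`, `roc.csv` and `predictive_values.csv` into
`demo/`. With seed 11 the association table starts:

```
   outcome             exposure        or   ci_low  ci_high            p
sle_status quartile_high_vs_low 11.853734 9.032181 15.55671 4.351396e-71
sle_status       grs_continuous  3.079733 2.772118  3.421484 1.856573e-97
      esrd quartile_high_vs_low  2.312625 1.023713  5.224352 4.376570e-02
```

SLE is ~12× more prevalent in the top GRS quartile than the bottom, and
end-stage renal disease among cases is enriched in the high quartile.
The ROC table shows the weighted score discriminating better than the
raw allele count (AUC 0.741 vs 0.687, DeLong p = 3.5×10⁻¹⁶), and
discrimination strongest for young-onset cases (stratum AUC 0.763 /
0.734 / 0.709 for onset <20 / 20–40 / >40 years). The survival table
reports, per event, affected counts, mean age at the event by quartile,
the Cox HR and the Gehan p — e.g. with this seed first organ damage
occurs at mean age 40.4 in the high quartile vs 46.3 in the low (HR
1.36, p = 0.003).

The same analyses run on real inputs (`slegrs report --genotypes
cohort.vcf --weights panel.tsv --phenotypes pheno.csv`): a VCF v4.2 or
dosage CSV, a TSV weight table (`snp_id chrom pos risk_allele
other_allele or`), and a phenotype CSV with `individual_id`, `is_case`
and the outcome columns.

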