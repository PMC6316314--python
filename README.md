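# nutrigrs

Gene–diet interaction analysis for small postprandial intervention
cohorts. The package targets the kind of nutrigenetic study in which
nondiabetic volunteers are genotyped at a handful of type-2-diabetes
(T2DM) susceptibility loci, eat a standardized carbohydrate test meal
before and after a dietary intervention (e.g. four weeks of daily
yogurt), and have their postprandial glucose and insulin responses
compared between genetically low- and high-risk groups.

It is written for biostatisticians and nutrition researchers who need
the full chain — scoring, index derivation, comparison statistics,
power — as tested, reusable code, plus a synthetic-cohort generator so
every stage can be exercised without access to raw trial data.

## What it computes

**Weighted genetic risk score.** Each biallelic locus *i* is recoded to
a risk-allele dosage *dᵢ* ∈ {0, 1, 2}; with per-allele diabetes odds
ratios ORᵢ,

> GRS = Σᵢ dᵢ  (0–10 over five loci),  wGRS = Σᵢ ln(ORᵢ)·dᵢ.

Subjects at or below the median wGRS form the L-GRS group, the rest
H-GRS. Genotype distributions are checked by a 1-df Pearson chi-square
test of Hardy–Weinberg equilibrium.

**Postprandial indices.** From glucose/insulin curves sampled over
0–120 min: trapezoid-rule AUCs on the windows 0–30, 30–120, 0–120 min
(total or baseline-subtracted incremental; additivity
AUC₀₋₃₀ + AUC₃₀₋₁₂₀ = AUC₀₋₁₂₀ holds exactly), and the fasting and
early-phase indices

> HOMA-IR = FPG·FSI/405,  HOMA-β = 360·FSI/(FPG − 63),
> IGI = ΔI₀₋₃₀/ΔG₀₋₃₀,  oral DI = IGI·(1/FSI),
> IncAUC_ins/glu = incremental Ins-AUC₀₋₁₂₀ / incremental Glu-AUC₀₋₁₂₀,

plus BMI and activity energy expenditure
PAEE = MET·min/day × 3.5 × 0.005 × weight.

**Comparison statistics.** Paired and pooled/Welch unpaired t tests
with 95% CIs, Pearson chi-square on contingency tables, ANCOVA-adjusted
group means (OLS with a group indicator plus covariates, evaluated at
covariate grand means), and paired-t power / minimum sample size from
the noncentral t distribution.

**Synthetic cohorts.** `simulate_cohort` draws genotypes under
Hardy–Weinberg equilibrium, builds wGRS-dependent postprandial curves
at two visits with a configurable intervention effect concentrated in
the high-risk group, and records the latent noise-free ground truth for
parameter-recovery testing. The default panel's odds ratios are
synthetic placeholders (see `examples/snp_panel_synthetic.json`); real
analyses must supply their own panel JSON.

## Worked example

```sh
nutrigrs simulate --seed 7 --out-dir demo
nutrigrs score --genotypes demo/genotypes.csv --panel demo/panel.json --out scores.csv
nutrigrs report --genotypes demo/genotypes.csv --curves demo/curves.csv \
    --clinical demo/clinical.csv --anthro demo/anthro.csv \
    --panel demo/panel.json --out-dir report
```

The `score` step prints `scored 32 subjects; median weighted GRS cutoff
1.042`: the cohort is split at wGRS = 1.042 into 16 L-GRS and 16 H-GRS
subjects. Selected rows of `report/table2.csv` (adjusted means with the
between-group ANCOVA p, and the H-group post-minus-baseline paired-t
difference with its 95% CI):

| outcome        | base L  | base H  | p between | diff H  | 95% CI            | p     |
|----------------|---------|---------|-----------|---------|-------------------|-------|
| auc_glu_0_120  | 1370.48 | 2247.83 | <0.01     | −465.09 | (−618.15, −312.03)| <0.01 |
| fsi            | 5.20    | 5.04    | 0.76      | −1.06   | (−1.66, −0.46)    | <0.01 |
| homa_ir        | 1.02    | 0.99    | 0.85      | −0.21   | (−0.34, −0.08)    | <0.01 |

Read: at baseline the high-risk group's incremental glucose area is
~880 mg/dL·min larger than the low-risk group's; after the simulated
intervention the high-risk group's glucose area falls by ~465 mg/dL·min
and its fasting insulin by ~1.1 units — the generator's configured
intervention effect (a 21% glucose-AUC reduction and a −1.55 fasting
insulin shift concentrated in the high-risk group) recovered by the
analysis chain. The companion `stats.json` keeps every statistic at
full precision and annotates the number of hypothesis tests performed
(no multiplicity adjustment is applied, matching the analysis style the
pipeline reproduces).

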