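# mmtsa

Genetic-model meta-analysis, trial sequential analysis (TSA) and
Wald-ratio Mendelian randomization (MR) for case-control genotype
counts.

`mmtsa` is for epidemiologists and biostatisticians who want to run —
or audit — the complete inference chain that links a biallelic variant
to a disease and, through the variant, an exposure to that disease.
The packaged dataset is the nine-study case-control literature on the
*MTHFR* C677T polymorphism and multiple myeloma (MM; 2,092 cases,
4,954 controls); the instrument anchors plasma homocysteine (Hcy),
which the 677T allele raises.

## The statistics

Per study, genotype counts (CC/CT/TT) collapse to a 2×2 table under five
genetic models — allele (T vs C), homozygous (TT vs CC), heterozygous
(CT vs CC), dominant (TT+CT vs CC), recessive (TT vs CT+CC) — giving a
log odds ratio with Woolf standard error, `se² = Σ 1/cell`.  Control
arms are checked for Hardy–Weinberg equilibrium by the 1-df Pearson χ².

Studies are pooled by Mantel–Haenszel (fixed effect) or
DerSimonian–Laird (random effects), chosen by the heterogeneity rule
*P*(Q) < 0.10 or I² > 50%.  Publication bias is probed by Egger's
regression (standardized effect on precision) and the Begg–Mazumdar
rank correlation.

TSA treats the cumulative meta-analysis as a sequentially monitored
trial: the diversity-adjusted required information size is

    RIS = (z₁₋α/₂ + z_pow)² · 2·p̄(1−p̄)/δ² · 1/(1−D²)

and the cumulative random-effects Z-curve is compared against two-sided
Lan–DeMets O'Brien–Fleming alpha-spending boundaries solved by
numerical integration over the non-crossing density.

The MR step is the single-instrument Wald ratio

    log OR_MM/Hcy = log OR_MM/allele / β_Hcy/allele ,

with the delta-method standard error (β = 0.158 SD ln-Hcy per T allele,
from the external GWAS meta-analysis of 44,147 individuals), plus the
analytic power `Φ(√(N·R²·p(1−p))·|ln OR| − z₁₋α/₂)`.

## Worked example

```python
>>> from mmtsa import (MetaAnalysis, WaldRatioMR, TrialSequentialAnalysis,
...                    TSAConfig, load_table1)
>>> studies = load_table1()
>>> pooled = MetaAnalysis(studies, "allele").fit()
>>> print(pooled.summary())
Pooled odds ratio
==============================================
genetic model    T vs C
pooling          random (dersimonian-laird)
studies          9
OR               1.1681
95% CI           (1.0184, 1.3399)
z / p            2.220 / 0.0264
Q (df, p)        15.051 (8, 0.0582)
I^2 / tau^2      46.8% / 0.01749
```

Carriers of each extra T allele have ~17% higher odds of MM
(OR 1.17, 95% CI 1.02–1.34); the moderate I² of 47% selected the
random-effects model.  Scaling by the instrument:

```python
>>> print(WaldRatioMR(pooled).fit().summary())
Mendelian randomization (Wald ratio)
==============================================
OR per SD ln-exposure   2.6739
95% CI                  (1.1223, 6.3706)
z / p                   2.220 / 0.02639
```

— a 1-SD genetically proxied increase in ln-homocysteine multiplies MM
risk ~2.7-fold.  And the sequential view:

```python
>>> print(TrialSequentialAnalysis(studies, TSAConfig(rri=0.1681, diversity=0.67)).fit().summary())
Trial sequential analysis
==============================================
required information size   2822 subjects
diversity D^2               67.0%
adjustment factor           3.030
accrued information         7046
information size reached    True
boundary crossed            True
final cumulative Z          2.220
adjusted 95% CI (OR)        (1.0183, 1.3399)
```

The accrued 7,046 subjects exceed the ~2,800 required, and the Z-curve
crossed the monitoring boundary: the evidence is sequentially firm, not
an artifact of repeated testing.

The same chain runs from the shell:

```bash
mmtsa run --out results/        # full bundle from the packaged config
mmtsa meta --input my_table.csv --model recessive
mmtsa simulate --n-studies 9 --seed 7 --out synth.csv
```

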