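# trioburden

Burden analysis of de novo mutation in trio cohorts of autism families —
simplex collections (one affected child, whole-blood DNA) against multiplex
collections (two or more affected children, largely lymphoblastoid cell-line
DNA). The package implements the full analysis pipeline as a reusable
library plus numbered analysis drivers, exercised end-to-end on a synthetic
trio cohort generator so every stage is testable without access-controlled
sequencing data.

## What it computes

**Cell-line drift QC.** Cultured lymphoblastoid cell lines (LCL) accumulate
somatic variants that mimic de novo calls. Each child is summarized by the
pair (power-adjusted de novo substitution count, mean alternative-allele
read ratio); a bivariate Gaussian fitted to whole-blood children defines a
99.9% ellipse (squared Mahalanobis distance ≤ χ²₀.₉₉₉(2) = 13.8155), and
children outside it are excluded as drifted.

**Effect annotation.** Small variants are classed as LGD (stop-gain,
frameshift, canonical splice site), synonymous (SYN), missense (MIS),
intercoding intronic substitutions/indels (ISB/IID — inside introns that
split two coding exons), or intergenic (IGSB/IGID); CNVs as coding /
genic-noncoding / intergenic, with single-gene events subclassed coding /
intercoding-intronic / peripheral (UTRs and UTR-splitting introns).

**Burden statistics.** For a subject class S against a presumed-neutral
normalization class N (which absorbs coverage, parental-age and residual
drift effects):

    ES.a = S.u · (N.a / N.u)
    AD   = 100 · (S.a − ES.a) / C.a      (ascertainment differential)
    PC   = 100 · (S.a − ES.a) / S.a      (percent contributory)

with one-sided p-values from a normal fitted to 1,000 label-permutation ADs,
95% percentile bootstrap intervals over child-level resampling,
mixed-normalization aggregation of disjoint classes, and direct permutation
comparison of two affected groups.

**Detection power.** Per-trio substitution power by simulating
Binomial(0.47, depth) alt reads through a stand-in trio genotyper; CNV power
by size by transplanting a male child's hemizygous X-chromosome read-depth
bins into an autosome and asking a z-score deletion finder to recover the
planted event.

**Contribution model.** Per-class ADs are tallied into the simplex
contribution S; the two-risk-class decomposition S = pLs·L + pHs·H is solved
for the low-risk contribution L; overall contributions combine the ranges
endpoint-wise, weighted by risk class or by registry case proportions.

## Worked example

```python
>>> import trioburden as tb
>>> r = tb.burden_from_totals(S_u=157, S_a=283, N_u=484, N_a=499, C_a=1869)
>>> round(r.ES_a, 1), round(r.AD, 2), round(r.PC, 1)
(161.9, 6.48, 42.8)
```

Reading: unaffected children carried 157 LGD and 484 synonymous de novo
events; affected children 283 LGD and 499 synonymous. Under the null the
affected should carry 157·(499/484) ≈ 161.9 LGDs; the 121 extra events mean
6.48% of the 1,869 affected children owe their diagnosis in part to a de
novo LGD, and 42.8% of the LGDs observed in affected children are
contributory.

The analysis drivers run the synthetic pipeline end to end and write their
tables under `results/`:

```
python analysis/01_simulate_cohort.py   # cohorts, calls, gene model, FASTA
python analysis/02_drift_filter.py     # drift ellipse fit + labels
python analysis/03_burden.py           # burden tests on drift-free children
python analysis/04_power.py            # substitution & CNV power curves
python analysis/05_contribution.py     # contribution tally and ranges
```

On the shipped seeds, step 02 excludes 50.5% of the simulated LCL samples
(and 0.2% of whole-blood samples); step 03 recovers the planted 6% LGD
differential as AD 9.95% (95% CI 4.70–15.04, p = 3 × 10⁻⁴); step 05 prints
the contribution tally 25% + 13% = 38%, L = 52–67%, and overall ranges
30.5–39.0% / 30.5–39.1%.

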