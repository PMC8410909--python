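# Methods

## The statistical model

The analysis asks whether a functional class of de novo variants is
over-represented in affected children relative to their expectation under no
contribution to diagnosis. Raw per-child counts are confounded by sequencing
coverage, parental age (de novo rates rise with paternal age) and — for
cell-line DNA — somatic drift. Rather than regressing these out, the design
normalizes by a presumed-neutral variant class measured in the same
children: synonymous events for coding classes, intergenic events for
intronic classes. Both members of a subject/normalization pair live in
comparable sequence context, so the covariates cancel in the ratio
N.a / N.u. For CNVs, where no abundant neutral event class exists, the
number of children serves as the normalization (equal-power detection is
then enforced upstream by the ≥ 4 kb size floor).

The two point statistics are the ascertainment differential
AD = 100·(S.a − ES.a)/C.a, read as "percent of affected children whose
diagnosis this class contributed to", and the percent contributory
PC = 100·(S.a − ES.a)/S.a, read as "fraction of the class's events in
affected that are causal". Both interpretations assume the expected number
of contributory events per child is below one, which is why the synthetic
generator never plants more than one extra event per child.

### Inference

The permutation p-value permutes affected/unaffected labels with group
sizes fixed; each child carries its (subject, normalization) count pair
through the shuffle and the expectation is recomputed per permutation. The
reported p is the upper tail of a normal fitted to the 1,000 permuted ADs —
so p-values below 1/1,000 are meaningful (they extrapolate the fitted
tail), and the p is never floored at 1/(n+1). The test-suite oracle checks
the fitted-normal p against the exhaustive permutation distribution on
8-child cohorts.

Bootstrap intervals are percentile 2.5/97.5 over 1,000 child-level
resamples within each group. The percentile method was chosen because the
statistic is a smooth ratio of sums with cohort-scale denominators; a BCa
refinement was considered and rejected as adding nothing at these sample
sizes. Permutation and bootstrap consume independent seeded streams, so
enabling one never perturbs the other.

Aggregation over disjoint classes (e.g. LGD plus coding CNVs) sums
per-class expectations at full precision before forming the AD, and the
joint permutation shuffles children once, carrying all class counts
together — this is what makes the aggregate test free of independence
assumptions between classes. Two affected groups are compared by permuting
children between them and using AD₁ − AD₂ (each against its fixed
unaffected baseline) as the statistic; the difference-of-ADs statistic was
chosen over a rate difference because it is the same scale on which the
per-group results are reported.

### Display conventions

Expected counts print at 1 decimal, AD/PC at 2 and 1 decimals respectively;
full precision is retained internally (the aggregate expectation 205.7 is
reproducible only from unrounded per-class expectations, 161.866 + 43.883).

## Drift filter

Each child is summarized by (observed substitutions / per-child detection
power, mean alternative-allele read ratio). A genuine heterozygous de novo
call sits near an allele ratio of 0.47 (slight reference bias); drifted
cell-line samples show inflated counts and a low-ratio mode because somatic
variants arise in a fraction of the cultured cells. The bivariate Gaussian
is fitted by plain sample moments on whole-blood children only (SSC and
AGRE jointly), on the raw variables — log-scaling seen in display contexts
is treated as plotting, not modelling. The pass region is Mahalanobis² ≤
χ²(2 df, 0.999) = 13.8155; boundary equality passes. Children with zero
substitutions have no defined mean ratio and are labelled INCOMPLETE,
excluded from both the fit and downstream groups. Classification is
affine-equivariant, so the units of either axis are immaterial.

## Effect annotation

Severity precedence is coding > splice site > intronic > intergenic, with
most-severe-wins across overlapping transcripts ("coding in any transcript"
matches the any-overlap convention used for CNV classes). Canonical splice
sites are the 2 bp at each intron end of a coding transcript. Intercoding
introns require both flanking exons to carry CDS in the *same* transcript
(the same-transcript reading of "an intron splitting two coding exons").
Codon consequences are computed from the spliced CDS with Biopython's
translation table; stop-gains are LGD, stop-losses are counted MIS (no
dedicated class exists for them). Frameshifting CDS indels (length mod
3 ≠ 0) are LGD; in-frame coding indels fall into OTHER — the small-variant
classes analysed simply have no slot for them and the burden analysis
ignores OTHER. Indels spanning a feature boundary are classed by the most
severe overlapped feature. chrX and chrY events are always OTHER, mirroring
the X-exclusion of the burden analysis. CNV size filtering retains events
with size ≥ 4,000 bp (inclusive).

## Synthetic cohort generator

The generator emulates what the analysis assumes about real trio WGS data:

* **Counts.** Per child, detected small de novo events are Poisson at
  (base_sub_rate + paternal_age_slope · father_age) · p_det(coverage),
  with p_det(c) = 1 − e^(−c/8) (≈ 0.98 at 30×, 0 at 0×). Class counts are
  drawn as independent Poissons per class — exactly equivalent to a Poisson
  total split multinomially, and Poisson dispersion per class becomes
  structural. Default per-child magnitudes (SYN ≈ 0.26, LGD ≈ 0.084,
  IID ≈ 2.1, IGID ≈ 3.1, ISB ≈ 20, IGSB ≈ 31) mirror a whole-genome simplex
  cohort; the total base rate of 65 events/child and a mild slope of 0.15
  events per paternal year keep those magnitudes at the default parental-age
  distribution (normal(33, 5) truncated to [18, 60]).
* **Reads.** Per variant, depth ~ Poisson(mean coverage, floored at 1) and
  alt reads ~ Binomial(0.47, depth) for clean children.
* **Drift.** A two-component mixture, not a continuum: each LCL child
  drifts with probability 0.55 (the fraction observed empirically in
  cell-line collections), multiplying its event rate by 5 and drawing
  per-variant allele ratios from Beta(2, 6) (mean 0.25). The multiplier and
  ratio shift are configuration, chosen to produce clearly separated count /
  ratio phases, not claims about real data.
* **Plants.** Each affected child receives at most one extra contributory
  event: class k with probability planted_AD[k]/100, via a single
  multinomial draw. This makes the planted AD the exact expectation of the
  recovered AD (verified unbiased to ±0.5 points over 200 replicates).
* **Placement.** A deterministic toy genome (two chromosomes, gene
  templates cycling UTR-rich coding / fully coding / noncoding) guarantees
  eligible regions for every class; candidate positions are precomputed per
  class and verified against the annotator, so a generated variant always
  annotates back to its intended class. `simulate_drift_stats` provides a
  placement-free fast path drawing the identical count/read model for
  drift-filter experiments at large n.

What the generator does *not* emulate: read-level data, haplotypes,
transmitted variation, locus-specific mutability, multi-event children
beyond Poisson co-occurrence, and real LCL drift physics. Passing tests
therefore demonstrate that the statistical machinery recovers what it
assumes, not that those assumptions hold in any particular dataset.

## Detection power

The published trio genotyper and the production CNV finders are out of
scope here; the power *procedures* are implemented around narrow stand-ins:

* The stand-in genotyper calls DENOVO when the child has ≥ 3 alt reads,
  both parents have zero alt reads, the natural-log likelihood ratio of a
  heterozygous-child trio (alt ratio 0.47) versus an all-reference trio
  (sequencing error 0.005) is ≥ 8, and a two-sided binomial consistency
  test of the child's allele ratio exceeds p = 0.001. Its score scale is
  its own; thresholds from other callers do not transfer.
* The deletion finder flags maximal runs of ≥ `min_consecutive_bins` bins
  with population z-score ≤ −`z_threshold` (zero-variance columns carry no
  signal; ≥ 20 samples required). On row-median-normalized Poisson bins at
  depth d, a hemizygous swap shifts each bin by about −0.5·√d standard
  deviations, which is what makes power rise steeply with size between 1
  and 10 kb at ~25-40×.

The region swap plants biologically realistic deletion signal — the male X
is a true single-copy territory in the same sample, so GC and mappability
biases travel with it. Masks (pseudoautosomal, telomeric, centromeric) are
inputs; the synthetic bin matrix masks its chromosome ends. Bin width
defaults to 100 bp; the size grid defaults to 1–10 kb in 1 kb steps (a
1–100 kb preset exists for wider sweeps). Problem sizes in the shipped
tests and drivers (hundreds of swaps per size, 10⁴ genotyper positions)
were chosen as the smallest that hold Monte-Carlo error visibly below the
effect sizes being asserted.

## Contribution model

Range arithmetic pairs lo↔lo and hi↔hi endpoints throughout, which is the
pairing that reproduces every printed derived range. The registry-weighted
overall estimate uses the unrounded multiplex case proportion
13,775/78,959 ≈ 0.1745. The multiplex contribution H is an input (9–11%),
not derived from the simplex range, since the rounding that produced it is
not specified. No uncertainty propagation beyond interval endpoints is
attempted: the inputs are themselves literature-grade point ranges without
usable standard errors.

## Interfaces

The package is organised as an analysis project: the `analysis/` drivers
are the command-line surface (simulate → drift-filter → burden → power →
contribution), each a thin script over library functions, writing TSV/text
tables under `results/`. No console-script entry point is installed.

## Known limitations

* The normal fit to permuted ADs extrapolates far tails; for counts this
  small-tailed the exhaustive-oracle agreement holds to ±0.1, but extreme
  quoted p-values (≪ 10⁻⁴) inherit normal-tail accuracy.
* The affected-group comparison has limited power at cohort scale: with a
  permutation null SD of ≈ 1.4 AD points at ~1,900 + 1,100 affected, a true
  4.5-point difference reaches p < 0.01 in only ~70-80% of replicates.
* Mean alternative-allele ratios are slightly non-Gaussian for children
  with few substitutions; at realistic counts (≥ 40 events/child) the
  ellipse's nominal 0.1% exclusion holds to binomial tolerance.
* The stand-in genotyper ignores genotyping error modes other than binomial
  read sampling (no mapping artifacts, no parental mosaicism), so absolute
  power values are optimistic; monotone comparisons across depths are the
  meaningful output.
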