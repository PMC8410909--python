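"""Synthetic trio cohorts with the statistical structure the burden analysis assumes.

The generator emulates, per child: a Poisson number of de novo small events
whose rate rises with paternal age and is thinned by a coverage-dependent
detection probability; a multinomial split of events over functional classes;
binomial alternative-allele read ratios around 0.47 for genuine heterozygous
calls; an optional lymphoblastoid-cell-line (LCL) drift mixture in which a
fraction of LCL samples carry inflated event counts and depressed allele
ratios; and a plantable excess of contributory classes in affected children
(at most one extra event per selected child).

Class counts are drawn as independent Poissons per class, which is exactly
the Poisson-total + multinomial-split model (thinning and splitting of a
Poisson process) and keeps per-class counts Poisson-dispersed by
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_io import ChildRecord, DeNovoCNV, DeNovoVariant, GeneModelTranscript
from .effect_annotation import EffectClass, GenomeAnnotation, annotate_small_variant

__all__ = [
    "CohortSpec",
    "ToyGenome",
    "make_toy_genome",
    "simulate_children",
    "simulate_class_counts",
    "simulate_denovo_calls",
    "detection_probability",
    "DEFAULT_CLASS_PROPORTIONS",
]

# Per-child event rates mirroring the magnitudes of a whole-genome simplex
# cohort (counts per unaffected child), normalized to proportions of the
# default total rate of 65 events/child. OTHER absorbs the remainder
# (UTR/noncoding-genic events that the burden analysis ignores).
_PER_CHILD_RATES = {
    EffectClass.LGD: 0.084,
    EffectClass.SYN: 0.258,
    EffectClass.MIS: 0.60,
    EffectClass.ISB: 20.18,
    EffectClass.IID: 2.09,
    EffectClass.IGSB: 31.10,
    EffectClass.IGID: 3.13,
}
_TOTAL_RATE = 65.0
DEFAULT_CLASS_PROPORTIONS: dict[EffectClass, float] = {
    **{k: v / _TOTAL_RATE for k, v in _PER_CHILD_RATES.items()},
    EffectClass.OTHER: 1.0 - sum(_PER_CHILD_RATES.values()) / _TOTAL_RATE,
}

_INDEL_CLASSES = {EffectClass.IID, EffectClass.IGID}


def detection_probability(coverage) -> np.ndarray:
    """Probability that a true de novo substitution is detected at a given
    mean coverage; saturating exponential, ~0.98 at 30x and 0 at 0x."""
    return 1.0 - np.exp(-np.asarray(coverage, dtype=float) / 8.0)


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n_affected: int
    n_unaffected: int
    collection: str = "SSC"
    dna_source_mix: float = 0.0  # fraction of children drawn from LCL DNA
    base_sub_rate: float = 65.0  # expected de novo small events per child
    paternal_age_slope: float = 0.15  # extra events per paternal year
    coverage_mean: float = 30.0
    coverage_sd: float = 5.0
    allele_ratio_p: float = 0.47
    class_proportions: Mapping[EffectClass, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    planted_AD: Mapping[EffectClass, float] = field(default_factory=dict)
    drift_fraction: float = 0.55
    drift_count_multiplier: float = 5.0
    drift_allele_ratio_beta: tuple[float, float] = (2.0, 6.0)
    cnv_rate: float = 0.08  # de novo CNVs per child
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, not 1")
        for k, v in self.planted_AD.items():
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"planted_AD[{k}] = {v} outside [0, 100]")
        if not 0.0 <= self.dna_source_mix <= 1.0:
            raise ValueError("dna_source_mix must be in [0, 1]")
        if self.drift_count_multiplier <= 1.0:
            raise ValueError("drift_count_multiplier must exceed 1")
        if self.paternal_age_slope < 0:
            raise ValueError("paternal_age_slope must be non-negative")


@dataclass
class ToyGenome:
    """A small two-chromosome genome for exercising the annotation classes.

    Guarantees at least one multi-exon coding transcript, one noncoding
    transcript and one UTR-containing transcript, plus intergenic gaps, so
    every functional class has an eligible placement region. chrX carries one
    gene so X-exclusion logic is exercisable.
    """

    chrom_lengths: dict[str, int]
    transcripts: list[GeneModelTranscript]
    sequences: dict[str, str]
    seed: int

    def __post_init__(self) -> None:
        self._annotation: GenomeAnnotation | None = None
        self._placements: dict | None = None

    @property
    def annotation(self) -> GenomeAnnotation:
        if self._annotation is None:
            self._annotation = GenomeAnnotation(
                self.transcripts, sequences=self.sequences, chrom_lengths=self.chrom_lengths
            )
        return self._annotation


# gene templates: (exons, cds, description) in coordinates relative to the
# gene start; spans are 2000 bp, genes are laid 6000 bp apart
_TEMPLATE_UTR = dict(  # 4 exons; intron1 splits the 5'UTR, introns 2-3 are intercoding
    exons=((0, 160), (300, 700), (900, 1300), (1500, 1900)),
    cds=(500, 1701),
)
_TEMPLATE_CODING = dict(  # fully coding 2-exon gene, one intercoding intron
    exons=((0, 600), (1200, 1800)),
    cds=(0, 1800),
)
_TEMPLATE_NONCODING = dict(exons=((0, 500), (1000, 1500)), cds=None)

_TEMPLATES = [_TEMPLATE_UTR, _TEMPLATE_CODING, _TEMPLATE_NONCODING]


def make_toy_genome(n_genes: int = 8, seed: int = 1) -> ToyGenome:
    """Build a deterministic toy genome with ``n_genes`` genes on chr1.

    Gene structures cycle through three templates (UTR-rich coding,
    fully-coding, noncoding) so that coding, intercoding-intronic,
    peripheral, noncoding and intergenic placements all exist.
    """
    if n_genes < 5:
        raise ValueError("need at least 5 genes to realize every effect class")
    rng = np.random.default_rng(seed)
    spacing, span = 6000, 2000
    chr1_len = n_genes * spacing + 4000
    chrx_len = 8000
    chrom_lengths = {"chr1": chr1_len, "chrX": chrx_len}
    sequences = {
        c: "".join(rng.choice(list("ACGT"), size=n)) for c, n in chrom_lengths.items()
    }
    transcripts = []
    for i in range(n_genes):
        tpl = _TEMPLATES[i % len(_TEMPLATES)]
        offset = 2000 + i * spacing
        exons = tuple((offset + s, offset + e) for s, e in tpl["exons"])
        if tpl["cds"] is None:
            cds = (exons[0][0], exons[0][0])
        else:
            cds = (offset + tpl["cds"][0], offset + tpl["cds"][1])
        transcripts.append(
            GeneModelTranscript(
                gene_symbol=f"G{i}",
                transcript_id=f"G{i}.t1",
                chrom="chr1",
                strand="+" if i % 2 == 0 else "-",
                tx_start=exons[0][0],
                tx_end=exons[-1][1],
                exons=exons,
                cds_start=cds[0],
                cds_end=cds[1],
            )
        )
    # one coding gene on chrX for the exclusion logic
    x_exons = ((2000, 2600), (3200, 3800))
    transcripts.append(
        GeneModelTranscript(
            gene_symbol="GX0",
            transcript_id="GX0.t1",
            chrom="chrX",
            strand="+",
            tx_start=2000,
            tx_end=3800,
            exons=x_exons,
            cds_start=2000,
            cds_end=3800,
        )
    )
    genome = ToyGenome(
        chrom_lengths=chrom_lengths, transcripts=transcripts, sequences=sequences, seed=seed
    )
    # constructive guarantee: every class must have at least one placement
    tables = _placement_tables(genome)
    missing = [k.value for k, v in tables.items() if len(v) == 0]
    if missing:
        raise ValueError(f"toy genome lacks placement regions for classes: {missing}")
    return genome


# ---------------------------------------------------------------------------
# Placement tables: for each class, concrete (pos, ref, alt) or interval
# candidates on chr1, built once per genome and verified against the
# annotator so generated variants always carry their intended class.
# ---------------------------------------------------------------------------


def _placement_tables(genome: ToyGenome) -> dict:
    if genome._placements is not None:
        return genome._placements
    ann = genome.annotation
    seq = genome.sequences["chr1"]
    bases = "ACGT"

    sub_candidates: dict[EffectClass, list[tuple[int, str, str]]] = {
        EffectClass.LGD: [],
        EffectClass.SYN: [],
        EffectClass.MIS: [],
    }
    cds_positions = set()
    splice_positions = set()
    intercoding: list[tuple[int, int]] = []
    transcript_spans: list[tuple[int, int]] = []
    utr_exonic: list[tuple[int, int]] = []
    for t in genome.transcripts:
        if t.chrom != "chr1":
            continue
        transcript_spans.append((t.tx_start, t.tx_end))
        for s, e in t.cds_intervals:
            cds_positions.update(range(s, e))
        if t.is_coding:
            for s, e in ann.splice_windows(t):
                splice_positions.update(range(s, e))
            intercoding.extend(ann.intercoding_introns(t))
        for s, e in t.exons:
            cs, ce = max(s, t.cds_start), min(e, t.cds_end)
            if cs >= ce:  # fully non-CDS exon (UTR or noncoding)
                utr_exonic.append((s, e))
            else:
                if s < cs:
                    utr_exonic.append((s, cs))
                if ce < e:
                    utr_exonic.append((ce, e))

    # codon-level classification of every possible CDS substitution
    for pos0 in sorted(cds_positions):
        ref = seq[pos0]
        for alt in bases:
            if alt == ref:
                continue
            v = DeNovoVariant(child_id="_", chrom="chr1", pos=pos0 + 1, ref=ref, alt=alt,
                              ref_reads=1, alt_reads=1)
            cls = annotate_small_variant(v, ann)
            if cls in sub_candidates:
                sub_candidates[cls].append((pos0, ref, alt))
    # splice-site substitutions are LGD too
    for pos0 in sorted(splice_positions - cds_positions):
        ref = seq[pos0]
        sub_candidates[EffectClass.LGD].append((pos0, ref, bases[(bases.index(ref) + 1) % 4]))

    # interval candidates: interiors away from splice windows (margin 4 bp
    # keeps a 2 bp indel clear of the canonical splice sites)
    margin = 4
    intercoding_interior = [(s + margin, e - margin) for s, e in intercoding if e - s > 2 * margin]

    merged = sorted(transcript_spans)
    intergenic: list[tuple[int, int]] = []
    cursor = 0
    for s, e in merged:
        if s - margin > cursor + margin:
            intergenic.append((cursor + margin, s - margin))
        cursor = max(cursor, e)
    if cursor + margin < len(seq) - margin:
        intergenic.append((cursor + margin, len(seq) - margin))

    tables = {
        EffectClass.LGD: sub_candidates[EffectClass.LGD],
        EffectClass.SYN: sub_candidates[EffectClass.SYN],
        EffectClass.MIS: sub_candidates[EffectClass.MIS],
        EffectClass.ISB: intercoding_interior,
        EffectClass.IID: intercoding_interior,
        EffectClass.IGSB: intergenic,
        EffectClass.IGID: intergenic,
        EffectClass.OTHER: utr_exonic,
    }
    genome._placements = tables
    return tables


def place_variant(
    genome: ToyGenome, effect: EffectClass, rng: np.random.Generator, child_id: str
) -> DeNovoVariant:
    """Draw one variant of the requested class at a class-consistent position."""
    tables = _placement_tables(genome)
    candidates = tables[effect]
    if not candidates:
        raise ValueError(f"no eligible placement interval for class {effect.value}")
    seq = genome.sequences["chr1"]
    bases = "ACGT"
    if effect in (EffectClass.LGD, EffectClass.SYN, EffectClass.MIS):
        pos0, ref, alt = candidates[rng.integers(len(candidates))]
        return DeNovoVariant(child_id=child_id, chrom="chr1", pos=pos0 + 1, ref=ref, alt=alt)
    s, e = candidates[rng.integers(len(candidates))]
    if effect in _INDEL_CLASSES:
        pos0 = int(rng.integers(s, e - 3))  # 2 bp deletion with VCF anchor base
        return DeNovoVariant(
            child_id=child_id, chrom="chr1", pos=pos0 + 1, ref=seq[pos0 : pos0 + 3], alt=seq[pos0]
        )
    pos0 = int(rng.integers(s, e))
    ref = seq[pos0]
    alt = bases[(bases.index(ref) + int(rng.integers(1, 4))) % 4]
    return DeNovoVariant(child_id=child_id, chrom="chr1", pos=pos0 + 1, ref=ref, alt=alt)


# ---------------------------------------------------------------------------
# Children and calls
# ---------------------------------------------------------------------------


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def simulate_children(spec: CohortSpec, seed: int | None = None) -> list[ChildRecord]:
    """Simulate one child per trio family with realistic covariates.

    Parental ages are normal(33, 5) truncated to [18, 60]; coverage is
    normal(coverage_mean, coverage_sd) floored at 5x; DNA source is LCL with
    probability ``dna_source_mix``; sexes alternate deterministically for a
    stable male fraction.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_affected + spec.n_unaffected
    mother = _truncated_normal(rng, 33.0, 5.0, 18.0, 60.0, n)
    father = _truncated_normal(rng, 33.0, 5.0, 18.0, 60.0, n)
    coverage = np.maximum(rng.normal(spec.coverage_mean, spec.coverage_sd, size=n), 5.0)
    lcl = rng.random(n) < spec.dna_source_mix
    children = []
    prefix = spec.collection.lower()
    for i in range(n):
        affected = i < spec.n_affected
        children.append(
            ChildRecord(
                child_id=f"{prefix}{i:05d}.{'p1' if affected else 's1'}",
                family_id=f"{prefix}{i:05d}",
                collection=spec.collection,
                affected=affected,
                sex="M" if i % 2 == 0 else "F",
                dna_source="LCL" if lcl[i] else "WB",
                mother_age_years=float(mother[i]),
                father_age_years=float(father[i]),
                mean_coverage=float(coverage[i]),
            )
        )
    return children


def simulate_class_counts(
    cohort: Sequence[ChildRecord], spec: CohortSpec, seed: int | None = None
) -> pd.DataFrame:
    """Per-child de novo event counts by functional class.

    Returns a DataFrame indexed by child_id with one integer column per
    :class:`EffectClass`, a ``CNV`` count column, and a boolean ``drifted``
    column. The detected event rate for child *i* is
    ``(base_sub_rate + paternal_age_slope * father_age_i) * p_det(coverage_i)``,
    multiplied by ``drift_count_multiplier`` for drifting LCL samples; class
    counts are independent Poissons at rate * proportion, and each affected
    child receives at most one extra planted event, of class *k* with
    probability ``planted_AD[k] / 100``.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = len(cohort)
    father = np.array([c.father_age_years for c in cohort])
    coverage = np.array([c.mean_coverage for c in cohort])
    affected = np.array([c.affected for c in cohort])
    lcl = np.array([c.dna_source == "LCL" for c in cohort])

    rate = (spec.base_sub_rate + spec.paternal_age_slope * father) * detection_probability(coverage)
    drifted = lcl & (rng.random(n) < spec.drift_fraction)
    rate = np.where(drifted, rate * spec.drift_count_multiplier, rate)

    classes = list(EffectClass)
    counts = {
        cls: rng.poisson(rate * spec.class_proportions.get(cls, 0.0)) for cls in classes
    }
    cnv_rate = np.where(drifted, spec.cnv_rate * spec.drift_count_multiplier, spec.cnv_rate)
    counts_cnv = rng.poisson(cnv_rate)

    if spec.planted_AD:
        plant_classes = list(spec.planted_AD)
        probs = np.array([spec.planted_AD[k] / 100.0 for k in plant_classes])
        if probs.sum() > 1.0 + 1e-12:
            raise ValueError("planted_AD probabilities sum above 100%")
        # one multinomial draw per affected child: class k or no plant
        full = np.append(probs, 1.0 - probs.sum())
        draws = rng.multinomial(1, full, size=int(affected.sum()))
        idx_affected = np.flatnonzero(affected)
        for j, cls in enumerate(plant_classes):
            counts[cls][idx_affected[draws[:, j] == 1]] += 1

    df = pd.DataFrame(
        {cls.value: counts[cls] for cls in classes},
        index=pd.Index([c.child_id for c in cohort], name="child_id"),
    )
    df["CNV"] = counts_cnv
    df["drifted"] = drifted
    return df


def simulate_drift_stats(
    cohort: Sequence[ChildRecord], spec: CohortSpec, seed: int | None = None
):
    """Per-child drift statistics without variant placement.

    Draws the same per-child substitution counts and read-support model as
    :func:`simulate_denovo_calls` but skips genomic placement, returning
    :class:`~trioburden.drift_filter.DriftStat` objects directly (the child's
    detection power is taken from the coverage model). Used for drift-filter
    experiments at cohort sizes where placing every variant is unnecessary.
    """
    from .drift_filter import DriftStat

    rng = np.random.default_rng(spec.seed if seed is None else seed)
    counts = simulate_class_counts(cohort, spec, seed=int(rng.integers(2**31)))
    sub_classes = [c.value for c in EffectClass if c not in _INDEL_CLASSES]
    a, b = spec.drift_allele_ratio_beta
    stats_out = []
    for child in cohort:
        row = counts.loc[child.child_id]
        n_subs = int(sum(row[c] for c in sub_classes))
        power = float(detection_probability(child.mean_coverage))
        if n_subs == 0:
            stats_out.append(DriftStat(child.child_id, 0, power, 0.0, None))
            continue
        depth = np.maximum(rng.poisson(child.mean_coverage, size=n_subs), 1)
        if bool(row["drifted"]):
            p = rng.beta(a, b, size=n_subs)
        else:
            p = spec.allele_ratio_p
        alt = rng.binomial(depth, p)
        mean_ratio = float(np.mean(alt / depth))
        stats_out.append(DriftStat(child.child_id, n_subs, power, n_subs / power, mean_ratio))
    return stats_out


def simulate_denovo_calls(
    cohort: Sequence[ChildRecord],
    genome: ToyGenome,
    spec: CohortSpec,
    seed: int | None = None,
) -> tuple[list[DeNovoVariant], list[DeNovoCNV]]:
    """Simulate placed de novo calls with read support for every child.

    Event counts come from :func:`simulate_class_counts`; each event is
    placed in a class-consistent region of the toy genome. Read depth per
    variant is Poisson at the child's mean coverage (floored at 1); the
    alternative read count is Binomial(``allele_ratio_p``, depth) for clean
    children and Binomial(r, depth) with r ~ Beta(*drift_allele_ratio_beta*)
    per variant for drifting children.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    counts = simulate_class_counts(cohort, spec, seed=int(rng.integers(2**31)))
    variants: list[DeNovoVariant] = []
    cnvs: list[DeNovoCNV] = []
    a, b = spec.drift_allele_ratio_beta
    chr1_len = genome.chrom_lengths["chr1"]
    from dataclasses import replace as _replace

    for child in cohort:
        row = counts.loc[child.child_id]
        drifted = bool(row["drifted"])
        for cls in EffectClass:
            k = int(row[cls.value])
            for _ in range(k):
                v = place_variant(genome, cls, rng, child.child_id)
                depth = max(int(rng.poisson(child.mean_coverage)), 1)
                p = rng.beta(a, b) if drifted else spec.allele_ratio_p
                alt = int(rng.binomial(depth, p))
                variants.append(
                    _replace(v, ref_reads=depth - alt, alt_reads=alt, effect=cls.value)
                )
        for _ in range(int(row["CNV"])):
            size = int(round(10 ** rng.uniform(3.0, 4.5)))  # 1-32 kb
            start = int(rng.integers(0, chr1_len - size))
            cnvs.append(
                DeNovoCNV(
                    child_id=child.child_id,
                    chrom="chr1",
                    start=start,
                    end=start + size,
                    change="DEL" if rng.random() < 0.5 else "DUP",
                )
            )
    return variants, cnvs
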