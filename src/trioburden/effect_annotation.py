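"""Functional effect classes for de novo small variants and CNVs.

Small variants are placed into one of eight classes:

* ``LGD`` — likely gene disrupting: stop-gain substitutions, frameshifting
  CDS indels (length mod 3 != 0), or changes to canonical splice sites
  (the 2 bp at each end of an intron of a coding transcript);
* ``SYN`` / ``MIS`` — synonymous / missense coding substitutions;
* ``ISB`` / ``IID`` — substitutions / small indels in *intercoding introns*
  (introns whose flanking exons both contain coding sequence in the same
  transcript), away from the splice sites;
* ``IGSB`` / ``IGID`` — intergenic substitutions / indels (outside every
  transcript);
* ``OTHER`` — everything else (UTR-exonic, noncoding-genic, in-frame coding
  indels, and all chrX events, which the burden analysis excludes).

Severity precedence is coding > splice site > intronic > intergenic, and a
position coding in *any* transcript is treated as coding (most-severe-wins
across transcripts).

CNVs get a top-level class (``CODING`` if any coding-exon base is touched,
else ``GENIC_NONCODING`` if any transcript is touched, else ``INTERGENIC``)
plus, when exactly one coding gene is overlapped, a single-gene subclass:
``CODING``, ``INTERCODING_INTRONIC`` (overlaps an intron splitting two coding
exons without touching coding bases), or ``PERIPHERAL`` (UTRs or the introns
that split UTRs).
"""

from __future__ import annotations

from enum import Enum
from typing import Iterable, Sequence

from Bio.Seq import Seq
from intervaltree import IntervalTree

from .cohort_io import DeNovoCNV, DeNovoVariant, GeneModelTranscript, get_logger

_log = get_logger(__name__)

SPLICE_SITE_BP = 2  # canonical splice-site window at each intron end (GT/AG)


class EffectClass(str, Enum):
    LGD = "LGD"
    SYN = "SYN"
    MIS = "MIS"
    ISB = "ISB"
    IID = "IID"
    IGSB = "IGSB"
    IGID = "IGID"
    OTHER = "OTHER"


class CnvEffectClass(str, Enum):
    INTERGENIC = "INTERGENIC"
    CODING = "CODING"
    GENIC_NONCODING = "GENIC_NONCODING"


class SingleGeneSubclass(str, Enum):
    CODING = "CODING"
    INTERCODING_INTRONIC = "INTERCODING_INTRONIC"
    PERIPHERAL = "PERIPHERAL"


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


class GenomeAnnotation:
    """Indexed view of a transcript set (plus optional genome sequence).

    Builds per-chromosome interval trees over transcripts and precomputes,
    per transcript, CDS intervals, canonical splice-site windows and the
    intercoding introns. ``sequences`` maps chromosome name to its sequence
    string; it is required only for codon-level classification of coding
    substitutions.
    """

    def __init__(
        self,
        transcripts: Sequence[GeneModelTranscript],
        sequences: dict[str, str] | None = None,
        chrom_lengths: dict[str, int] | None = None,
    ):
        self.transcripts = list(transcripts)
        self.sequences = sequences or {}
        self.chrom_lengths = dict(chrom_lengths or {})
        for chrom, seq in self.sequences.items():
            self.chrom_lengths.setdefault(chrom, len(seq))
        self._tree: dict[str, IntervalTree] = {}
        for t in self.transcripts:
            self._tree.setdefault(t.chrom, IntervalTree()).addi(t.tx_start, t.tx_end, t)
        # per-transcript structural caches
        self._splice: dict[str, list[tuple[int, int]]] = {}
        self._intercoding: dict[str, list[tuple[int, int]]] = {}
        self._cds_seq: dict[str, str] = {}
        self._cds_index: dict[str, dict[int, int]] = {}
        for t in self.transcripts:
            if t.is_coding:
                windows = []
                for s, e in t.introns:
                    windows.append((s, min(s + SPLICE_SITE_BP, e)))
                    windows.append((max(e - SPLICE_SITE_BP, s), e))
                self._splice[t.transcript_id] = windows
                inter = []
                for i, (s, e) in enumerate(t.introns):
                    left, right = t.exons[i], t.exons[i + 1]
                    if _overlaps_cds(left, t) and _overlaps_cds(right, t):
                        inter.append((s, e))
                self._intercoding[t.transcript_id] = inter

    # -- lookups ---------------------------------------------------------

    def transcripts_at(self, chrom: str, start: int, end: int) -> list[GeneModelTranscript]:
        tree = self._tree.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]

    def intercoding_introns(self, t: GeneModelTranscript) -> list[tuple[int, int]]:
        return self._intercoding.get(t.transcript_id, [])

    def splice_windows(self, t: GeneModelTranscript) -> list[tuple[int, int]]:
        return self._splice.get(t.transcript_id, [])

    # -- codon machinery -------------------------------------------------

    def _cds_layout(self, t: GeneModelTranscript) -> tuple[str, dict[int, int]]:
        """Spliced CDS sequence (coding-strand orientation) and the map from
        genomic position to CDS index."""
        if t.transcript_id in self._cds_seq:
            return self._cds_seq[t.transcript_id], self._cds_index[t.transcript_id]
        seq = self.sequences.get(t.chrom)
        if seq is None:
            raise ValueError(f"no sequence available for {t.chrom}; cannot classify coding change")
        positions: list[int] = []
        for s, e in t.cds_intervals:
            positions.extend(range(s, e))
        genomic = "".join(seq[p] for p in positions)
        if t.strand == "-":
            positions = positions[::-1]
            genomic = genomic.translate(_COMPLEMENT)[::-1]
        index = {p: i for i, p in enumerate(positions)}
        self._cds_seq[t.transcript_id] = genomic
        self._cds_index[t.transcript_id] = index
        return genomic, index

    def codon_change(self, t: GeneModelTranscript, pos0: int, ref: str, alt: str) -> tuple[str, str]:
        """Reference and mutated codon for a substitution at 0-based ``pos0``."""
        cds, index = self._cds_layout(t)
        i = index[pos0]
        base = alt.upper() if t.strand == "+" else alt.upper().translate(_COMPLEMENT)
        k = i // 3
        codon = cds[3 * k : 3 * k + 3]
        mutated = codon[: i % 3] + base + codon[i % 3 + 1 :]
        return codon, mutated


def _overlaps_cds(exon: tuple[int, int], t: GeneModelTranscript) -> bool:
    return max(exon[0], t.cds_start) < min(exon[1], t.cds_end)


def _as_annotation(genome) -> GenomeAnnotation:
    """Accept a GenomeAnnotation, a ToyGenome-like object, or a transcript list."""
    if isinstance(genome, GenomeAnnotation):
        return genome
    ann = getattr(genome, "annotation", None)
    if isinstance(ann, GenomeAnnotation):
        return ann
    if hasattr(genome, "transcripts"):
        return GenomeAnnotation(
            genome.transcripts,
            sequences=getattr(genome, "sequences", None),
            chrom_lengths=getattr(genome, "chrom_lengths", None),
        )
    return GenomeAnnotation(list(genome))


def _variant_span(v: DeNovoVariant) -> tuple[int, int]:
    """Affected genomic interval (0-based half-open).

    Substitutions cover one base. Deletions cover the deleted bases after the
    VCF anchor; insertions the two bases flanking the insertion point.
    """
    pos0 = v.pos - 1
    if v.var_type == "SUB":
        return pos0, pos0 + 1
    if len(v.ref) > len(v.alt):  # deletion: anchored, affected bases follow
        return pos0 + 1, pos0 + len(v.ref)
    return pos0, pos0 + 2  # insertion between pos0 and pos0+1


def annotate_small_variant(v: DeNovoVariant, genome) -> EffectClass:
    """Assign the functional class of one small de novo variant."""
    ann = _as_annotation(genome)
    if v.chrom in {"chrX", "chrY"}:
        return EffectClass.OTHER
    length = ann.chrom_lengths.get(v.chrom)
    if length is not None and v.pos > length:
        raise ValueError(f"position {v.chrom}:{v.pos} beyond chromosome length {length}")
    start, end = _variant_span(v)
    hits = ann.transcripts_at(v.chrom, start, end)
    is_sub = v.var_type == "SUB"

    # coding
    coding_hits = [
        t for t in hits if t.is_coding and any(max(s, start) < min(e, end) for s, e in t.cds_intervals)
    ]
    if coding_hits:
        if not is_sub:
            shift = abs(len(v.ref) - len(v.alt))
            return EffectClass.LGD if shift % 3 != 0 else EffectClass.OTHER
        severity = EffectClass.SYN
        for t in coding_hits:
            codon, mutated = ann.codon_change(t, start, v.ref, v.alt)
            ref_aa = str(Seq(codon).translate())
            alt_aa = str(Seq(mutated).translate())
            if alt_aa == "*" and ref_aa != "*":
                return EffectClass.LGD
            if alt_aa != ref_aa:
                severity = EffectClass.MIS
        return severity

    # canonical splice sites of coding transcripts
    for t in hits:
        for s, e in ann.splice_windows(t):
            if max(s, start) < min(e, end):
                return EffectClass.LGD

    # intercoding intronic
    for t in hits:
        for s, e in ann.intercoding_introns(t):
            if start >= s and end <= e:
                return EffectClass.ISB if is_sub else EffectClass.IID

    if hits:
        return EffectClass.OTHER

    return EffectClass.IGSB if is_sub else EffectClass.IGID


def annotate_cnv(c: DeNovoCNV, genome) -> DeNovoCNV:
    """Return a copy of ``c`` with CNV class, gene count and subclass filled in.

    Overlap semantics are any-bp. ``n_genes_hit`` counts distinct gene
    symbols whose transcript the event touches; the single-gene subclass is
    assigned only when exactly one *coding* gene is touched.
    """
    from dataclasses import replace

    ann = _as_annotation(genome)
    hits = ann.transcripts_at(c.chrom, c.start, c.end)
    genes = {t.gene_symbol for t in hits}
    coding_genes = {t.gene_symbol for t in hits if t.is_coding}

    touches_cds = any(
        max(s, c.start) < min(e, c.end)
        for t in hits
        if t.is_coding
        for s, e in t.cds_intervals
    )
    if touches_cds:
        top = CnvEffectClass.CODING
    elif hits:
        top = CnvEffectClass.GENIC_NONCODING
    else:
        top = CnvEffectClass.INTERGENIC

    subclass = None
    if len(coding_genes) == 1:
        if touches_cds:
            subclass = SingleGeneSubclass.CODING
        else:
            touches_intercoding = any(
                max(s, c.start) < min(e, c.end)
                for t in hits
                if t.is_coding
                for s, e in ann.intercoding_introns(t)
            )
            if touches_intercoding:
                subclass = SingleGeneSubclass.INTERCODING_INTRONIC
            else:
                subclass = SingleGeneSubclass.PERIPHERAL

    return replace(
        c,
        cnv_effect=top.value,
        single_gene_subclass=subclass.value if subclass else None,
        n_genes_hit=len(genes),
    )


def filter_events(
    events: Iterable,
    min_cnv_size: int = 4000,
    exclude_chrX: bool = True,
    exclude_splice_for_IID: bool = True,
    genome=None,
):
    """Apply the burden-analysis event filters, preserving input order.

    CNVs smaller than ``min_cnv_size`` (inclusive ``>=`` retention) are
    dropped; chrX (and chrY) events are dropped when ``exclude_chrX``. With
    ``exclude_splice_for_IID`` and a genome supplied, intronic events inside
    canonical splice-site windows are dropped as a belt-and-braces check (the
    annotation precedence already routes those to LGD). Removal counts are
    logged by reason.
    """
    removed = {"size": 0, "chrX": 0, "splice": 0}
    ann = _as_annotation(genome) if genome is not None else None
    kept = []
    for ev in events:
        if exclude_chrX and ev.chrom in {"chrX", "chrY"}:
            removed["chrX"] += 1
            continue
        if isinstance(ev, DeNovoCNV):
            if ev.size_bp < min_cnv_size:
                removed["size"] += 1
                continue
        elif (
            exclude_splice_for_IID
            and ann is not None
            and getattr(ev, "effect", None) in {EffectClass.ISB.value, EffectClass.IID.value}
        ):
            start, end = _variant_span(ev)
            in_splice = any(
                max(s, start) < min(e, end)
                for t in ann.transcripts_at(ev.chrom, start, end)
                for s, e in ann.splice_windows(t)
            )
            if in_splice:
                removed["splice"] += 1
                continue
        kept.append(ev)
    if any(removed.values()):
        _log.info(
            "filter_events removed %d by size, %d on chrX/Y, %d at splice sites",
            removed["size"],
            removed["chrX"],
            removed["splice"],
        )
    return kept
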