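"""Functional classification against constructed cases and a brute-force oracle."""

import numpy as np
import pytest

from trioburden.cohort_io import DeNovoCNV, DeNovoVariant, GeneModelTranscript
from trioburden.effect_annotation import (
    CnvEffectClass,
    EffectClass,
    GenomeAnnotation,
    SingleGeneSubclass,
    annotate_cnv,
    annotate_small_variant,
    filter_events,
)
from trioburden.synthetic_cohort import place_variant


def _mini_genome():
    """One 2-exon fully coding gene on a 60 bp chromosome with known codons.

    Exon1 (10,22) spells ATG CAA CTT AAA; intron (22,34); exon2 (34,46).
    """
    seq = list("A" * 60)
    seq[10:22] = "ATGCAACTTAAA"
    seq[22:34] = "GTGGGGGGGGAG"  # intron with GT...AG ends
    seq[34:46] = "ATGGTTCCTTGA"
    t = GeneModelTranscript(
        gene_symbol="MINI",
        transcript_id="MINI.t1",
        chrom="chr5",
        strand="+",
        tx_start=10,
        tx_end=46,
        exons=((10, 22), (34, 46)),
        cds_start=10,
        cds_end=46,
    )
    return GenomeAnnotation([t], sequences={"chr5": "".join(seq)})


def _v(pos, ref, alt, chrom="chr5"):
    return DeNovoVariant("c", chrom, pos, ref, alt, 5, 5)


class TestSmallVariantClasses:
    @pytest.mark.parametrize(
        "pos, ref, alt, expected",
        [
            (14, "C", "T", EffectClass.LGD),  # CAA -> TAA stop gain
            (19, "T", "C", EffectClass.SYN),  # CTT -> CTC (Leu)
            (12, "G", "C", EffectClass.MIS),  # ATG -> ATC (Met -> Ile)
            (23, "G", "A", EffectClass.LGD),  # donor splice site (+1 of intron)
            (33, "G", "C", EffectClass.LGD),  # acceptor splice site
            (28, "G", "A", EffectClass.ISB),  # intercoding intron interior
            (3, "A", "T", EffectClass.IGSB),  # intergenic substitution
        ],
    )
    def test_substitution_classes(self, pos, ref, alt, expected):
        assert annotate_small_variant(_v(pos, ref, alt), _mini_genome()) is expected

    def test_indel_classes(self):
        ann = _mini_genome()
        # 2 bp deletion wholly inside the intron, > 2 bp from both boundaries
        assert annotate_small_variant(_v(26, "GGG", "G"), ann) is EffectClass.IID
        # intergenic deletion
        assert annotate_small_variant(_v(2, "AAA", "A"), ann) is EffectClass.IGID
        # frameshifting CDS deletion
        assert annotate_small_variant(_v(15, "AAC", "A"), ann) is EffectClass.LGD
        # in-frame CDS deletion is no analysis class
        assert annotate_small_variant(_v(14, "CAAC", "C"), ann) is EffectClass.OTHER

    def test_chrX_always_other(self, toy_genome):
        assert annotate_small_variant(_v(2500, "A", "T", "chrX"), toy_genome) is EffectClass.OTHER

    def test_position_beyond_chromosome_raises(self):
        with pytest.raises(ValueError, match="beyond"):
            annotate_small_variant(_v(100, "A", "T"), _mini_genome())

    def test_strand_does_not_affect_interval_classes(self):
        """Flipping a transcript's strand changes codon reading but never the
        intronic/intergenic interval classes."""
        for strand in "+-":
            seq = "A" * 100
            t = GeneModelTranscript("G", "G.t", "chr7", strand, 10, 90,
                                    ((10, 40), (60, 90)), 10, 90)
            ann = GenomeAnnotation([t], sequences={"chr7": seq})
            assert annotate_small_variant(_v(50, "A", "T", "chr7"), ann) is EffectClass.ISB
            assert annotate_small_variant(_v(5, "A", "T", "chr7"), ann) is EffectClass.IGSB


class TestOracleEquivalence:
    """A brute-force annotator written from scratch must agree with the
    package on random placements over the toy genome."""

    @staticmethod
    def _brute_force(v, genome):
        CODONS = {}
        bases = "TCAG"
        aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
        i = 0
        for b1 in bases:
            for b2 in bases:
                for b3 in bases:
                    CODONS[b1 + b2 + b3] = aas[i]
                    i += 1
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        if v.chrom in ("chrX", "chrY"):
            return EffectClass.OTHER
        is_sub = len(v.ref) == 1 and len(v.alt) == 1
        pos0 = v.pos - 1
        if is_sub:
            span = (pos0, pos0 + 1)
        elif len(v.ref) > len(v.alt):
            span = (pos0 + 1, pos0 + len(v.ref))
        else:
            span = (pos0, pos0 + 2)

        def hits(lo, hi):
            return max(lo, span[0]) < min(hi, span[1])

        ts = [t for t in genome.transcripts
              if t.chrom == v.chrom and hits(t.tx_start, t.tx_end)]
        coding = []
        for t in ts:
            for s, e in t.cds_intervals:
                if hits(s, e):
                    coding.append(t)
                    break
        if coding:
            if not is_sub:
                return EffectClass.LGD if abs(len(v.ref) - len(v.alt)) % 3 else EffectClass.OTHER
            worst = EffectClass.SYN
            for t in coding:
                cds_pos = [p for s, e in t.cds_intervals for p in range(s, e)]
                seq = "".join(genome.sequences[t.chrom][p] for p in cds_pos)
                if t.strand == "-":
                    cds_pos = cds_pos[::-1]
                    seq = "".join(comp[c] for c in reversed(seq))
                i = cds_pos.index(pos0)
                alt = v.alt if t.strand == "+" else comp[v.alt]
                k = 3 * (i // 3)
                ref_codon = seq[k : k + 3]
                alt_codon = ref_codon[: i % 3] + alt + ref_codon[i % 3 + 1 :]
                ra, aa = CODONS[ref_codon], CODONS[alt_codon]
                if aa == "*" and ra != "*":
                    return EffectClass.LGD
                if aa != ra:
                    worst = EffectClass.MIS
            return worst
        for t in ts:
            if t.cds_end > t.cds_start:
                for s, e in zip([x[1] for x in t.exons[:-1]], [x[0] for x in t.exons[1:]]):
                    if hits(s, s + 2) or hits(e - 2, e):
                        return EffectClass.LGD
        for t in ts:
            if t.cds_end <= t.cds_start:
                continue
            exs = t.exons
            for i in range(len(exs) - 1):
                l_cds = max(exs[i][0], t.cds_start) < min(exs[i][1], t.cds_end)
                r_cds = max(exs[i + 1][0], t.cds_start) < min(exs[i + 1][1], t.cds_end)
                s, e = exs[i][1], exs[i + 1][0]
                if l_cds and r_cds and span[0] >= s and span[1] <= e:
                    return EffectClass.ISB if is_sub else EffectClass.IID
        if ts:
            return EffectClass.OTHER
        return EffectClass.IGSB if is_sub else EffectClass.IGID

    def test_small_variants_agree_with_oracle(self, toy_genome, rng):
        for _ in range(500):
            cls = list(EffectClass)[rng.integers(len(EffectClass))]
            v = place_variant(toy_genome, cls, rng, "c")
            assert annotate_small_variant(v, toy_genome) == self._brute_force(v, toy_genome)

    def test_random_positions_agree_with_oracle(self, toy_genome, rng):
        seq = toy_genome.sequences["chr1"]
        for _ in range(300):
            pos0 = int(rng.integers(0, len(seq) - 4))
            ref = seq[pos0]
            if rng.random() < 0.6:
                alt = "ACGT"[("ACGT".index(ref) + int(rng.integers(1, 4))) % 4]
                v = _v(pos0 + 1, ref, alt, "chr1")
            else:
                v = _v(pos0 + 1, seq[pos0 : pos0 + 3], seq[pos0], "chr1")
            assert annotate_small_variant(v, toy_genome) == self._brute_force(v, toy_genome)

    def test_cnv_labels_agree_with_interval_scan(self, toy_genome, rng):
        for _ in range(300):
            start = int(rng.integers(0, toy_genome.chrom_lengths["chr1"] - 100))
            size = int(rng.integers(50, 8000))
            c = DeNovoCNV("c", "chr1", start, start + size, "DEL")
            got = annotate_cnv(c, toy_genome)
            # oracle: direct scans over the transcript list
            ts = [t for t in toy_genome.transcripts
                  if t.chrom == "chr1" and max(t.tx_start, c.start) < min(t.tx_end, c.end)]
            genes = {t.gene_symbol for t in ts}
            cds_hit = any(
                max(s, c.start) < min(e, c.end) for t in ts for s, e in t.cds_intervals
            )
            if cds_hit:
                top = CnvEffectClass.CODING
            elif ts:
                top = CnvEffectClass.GENIC_NONCODING
            else:
                top = CnvEffectClass.INTERGENIC
            assert got.cnv_effect == top.value
            assert got.n_genes_hit == len(genes)


class TestCnvSubclasses:
    def test_whole_gene_cnv_is_coding_single_gene(self, toy_genome):
        t = next(x for x in toy_genome.transcripts if x.gene_symbol == "G1")
        c = annotate_cnv(DeNovoCNV("c", "chr1", t.tx_start - 50, t.tx_end + 50, "DEL"), toy_genome)
        assert c.cnv_effect == CnvEffectClass.CODING.value
        assert c.n_genes_hit == 1
        assert c.single_gene_subclass == SingleGeneSubclass.CODING.value

    def test_intercoding_intron_cnv(self, toy_genome):
        t = next(x for x in toy_genome.transcripts if x.gene_symbol == "G1")  # fully coding 2-exon
        (intron,) = t.introns
        c = annotate_cnv(DeNovoCNV("c", "chr1", intron[0] + 10, intron[1] - 10, "DEL"), toy_genome)
        assert c.cnv_effect == CnvEffectClass.GENIC_NONCODING.value
        assert c.single_gene_subclass == SingleGeneSubclass.INTERCODING_INTRONIC.value

    def test_utr_splitting_intron_cnv_is_peripheral(self, toy_genome):
        # G0 uses the UTR template: intron 1 splits the 5' UTR
        t = next(x for x in toy_genome.transcripts if x.gene_symbol == "G0")
        s, e = t.introns[0]
        c = annotate_cnv(DeNovoCNV("c", "chr1", s + 5, e - 5, "DEL"), toy_genome)
        assert c.cnv_effect == CnvEffectClass.GENIC_NONCODING.value
        assert c.single_gene_subclass == SingleGeneSubclass.PERIPHERAL.value

    def test_intergenic_cnv(self, toy_genome):
        c = annotate_cnv(DeNovoCNV("c", "chr1", 10, 500, "DEL"), toy_genome)
        assert c.cnv_effect == CnvEffectClass.INTERGENIC.value
        assert c.n_genes_hit == 0 and c.single_gene_subclass is None


class TestFilters:
    def test_cnv_size_threshold_is_inclusive(self):
        cnvs = [
            DeNovoCNV("c", "chr1", 0, 3999, "DEL"),
            DeNovoCNV("c", "chr1", 0, 4000, "DEL"),
            DeNovoCNV("c", "chr1", 0, 4001, "DEL"),
        ]
        kept = filter_events(cnvs, min_cnv_size=4000)
        assert [k.size_bp for k in kept] == [4000, 4001]

    def test_chrX_events_removed_and_order_preserved(self):
        events = [
            DeNovoVariant("c", "chr1", 10, "A", "T", 1, 1, effect="LGD"),
            DeNovoVariant("c", "chrX", 10, "A", "T", 1, 1, effect="LGD"),
            DeNovoVariant("c", "chr2", 10, "A", "T", 1, 1, effect="SYN"),
        ]
        kept = filter_events(events)
        assert [e.chrom for e in kept] == ["chr1", "chr2"]

    def test_retained_count_matches_brute_force(self, toy_genome, rng):
        cnvs = []
        for _ in range(200):
            start = int(rng.integers(0, 20000))
            size = int(rng.integers(1000, 10000))
            chrom = "chrX" if rng.random() < 0.1 else "chr1"
            cnvs.append(DeNovoCNV("c", chrom, start, start + size, "DEL"))
        kept = filter_events(cnvs, min_cnv_size=4000)
        expected = sum(1 for c in cnvs if c.size_bp >= 4000 and c.chrom != "chrX")
        assert len(kept) == expected
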