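#!/usr/bin/env python
"""Simulate the study cohorts and write every on-disk artifact.

Two cohorts are generated on a shared toy genome: a simplex-like collection
(whole-blood DNA, affected and unaffected siblings, a planted 6% LGD
differential in the affected) and a multiplex-like collection (mostly LCL
DNA with cell-line drift contamination, a planted 1.5% LGD differential,
no usable unaffected siblings). Artifacts go to results/sim/.
"""

from pathlib import Path

from trioburden import (
    CohortSpec,
    make_toy_genome,
    simulate_children,
    simulate_denovo_calls,
    write_gene_model,
    write_pedigree,
    write_variant_table,
)
from trioburden.effect_annotation import EffectClass

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"

SSC_SPEC = CohortSpec(
    n_affected=400, n_unaffected=400, collection="SSC",
    planted_AD={EffectClass.LGD: 6.0}, seed=101,
)
AGRE_SPEC = CohortSpec(
    n_affected=250, n_unaffected=0, collection="AGRE",
    dna_source_mix=0.85, drift_fraction=0.55, drift_count_multiplier=5.0,
    planted_AD={EffectClass.LGD: 1.5}, seed=102,
)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome = make_toy_genome(n_genes=8, seed=1)
    write_gene_model(genome.transcripts, OUT / "gene_model.bed")
    with open(OUT / "genome.fa", "w") as fh:
        for chrom, seq in genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")

    for label, spec in [("ssc", SSC_SPEC), ("agre", AGRE_SPEC)]:
        cohort = simulate_children(spec)
        variants, cnvs = simulate_denovo_calls(cohort, genome, spec)
        write_pedigree(cohort, OUT / f"{label}_pedigree.tsv")
        write_variant_table(variants, OUT / f"{label}_small_variants.tsv", kind="SMALL")
        write_variant_table(cnvs, OUT / f"{label}_cnvs.tsv", kind="CNV")
        n_drift_eligible = sum(c.dna_source == "LCL" for c in cohort)
        print(
            f"{label}: {len(cohort)} children ({sum(c.affected for c in cohort)} affected, "
            f"{n_drift_eligible} LCL), {len(variants)} small de novo calls, "
            f"{len(cnvs)} de novo CNVs"
        )
    print(f"wrote artifacts to {OUT}")


if __name__ == "__main__":
    main()
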