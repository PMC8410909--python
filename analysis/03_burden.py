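#!/usr/bin/env python
"""Burden analysis on the drift-filtered cohorts.

Keeps only drift-free children, re-annotates every call against the gene
model, applies the event filters (chrX exclusion, 4 kb CNV floor), and runs
the burden machinery: LGD normalized by synonymous, intercoding intronic
indels normalized by intergenic indels, coding CNVs normalized by child
count, and the mixed-normalization LGD + coding-CNV aggregate. The simplex
affected are tested against their unaffected siblings; the multiplex
affected are tested against the same simplex unaffected baseline and
directly against the simplex affected. Writes results/burden.tsv.
"""

from collections import defaultdict
from pathlib import Path

import numpy as np
import pandas as pd

from trioburden import (
    BurdenInput,
    NormalizationMode,
    aggregate_burden,
    annotate_cnv,
    annotate_small_variant,
    burden_test,
    compare_affected_groups,
    filter_events,
    read_gene_model,
    read_pedigree,
    read_variant_table,
)
from trioburden.effect_annotation import GenomeAnnotation

RESULTS = Path(__file__).resolve().parent.parent / "results"
SIM = RESULTS / "sim"
SEED = 7


def _counts(children, events_by_child, key):
    return np.array([events_by_child[c.child_id][key] for c in children])


def main() -> None:
    from Bio import SeqIO

    sequences = {rec.id: str(rec.seq) for rec in SeqIO.parse(SIM / "genome.fa", "fasta")}
    genome = GenomeAnnotation(read_gene_model(SIM / "gene_model.bed"), sequences=sequences)
    labels = pd.read_csv(RESULTS / "drift_labels.tsv", sep="\t").set_index("child_id")["label"]

    groups = {}
    events_by_child: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for label in ("ssc", "agre"):
        cohort = [c for c in read_pedigree(SIM / f"{label}_pedigree.tsv")
                  if labels[c.child_id] == "PASS"]
        groups[f"{label}_affected"] = [c for c in cohort if c.affected]
        groups[f"{label}_unaffected"] = [c for c in cohort if not c.affected]

        small = read_variant_table(SIM / f"{label}_small_variants.tsv", kind="SMALL")
        small = [v for v in small if labels[v.child_id] == "PASS"]
        from dataclasses import replace
        small = [replace(v, effect=annotate_small_variant(v, genome).value) for v in small]
        small = filter_events(small, genome=genome)
        for v in small:
            events_by_child[v.child_id][v.effect] += 1

        cnvs = [annotate_cnv(c, genome)
                for c in read_variant_table(SIM / f"{label}_cnvs.tsv", kind="CNV")
                if labels[c.child_id] == "PASS"]
        cnvs = filter_events(cnvs, min_cnv_size=4000)
        for c in cnvs:
            events_by_child[c.child_id]["CNV_" + c.cnv_effect] += 1

    ssc_a, ssc_u = groups["ssc_affected"], groups["ssc_unaffected"]
    agre_a = groups["agre_affected"]
    print(f"drift-free children: SSC {len(ssc_a)}+{len(ssc_u)}, AGRE {len(agre_a)} affected")

    rows = []
    comparisons = [
        ("SSC LGD vs SYN", ssc_a, "LGD", "SYN", NormalizationMode.EVENT_CLASS),
        ("AGRE LGD vs SYN", agre_a, "LGD", "SYN", NormalizationMode.EVENT_CLASS),
        ("SSC IID vs IGID", ssc_a, "IID", "IGID", NormalizationMode.EVENT_CLASS),
        ("SSC coding CNV", ssc_a, "CNV_CODING", None, NormalizationMode.CHILD_COUNT),
    ]
    inputs = {}
    for name, affected, subject, norm, mode in comparisons:
        inp = BurdenInput.from_counts(
            _counts(affected, events_by_child, subject),
            _counts(ssc_u, events_by_child, subject),
            _counts(affected, events_by_child, norm) if norm else None,
            _counts(ssc_u, events_by_child, norm) if norm else None,
            mode=mode,
        )
        inputs[name] = inp
        r = burden_test(inp, n_perm=1000, n_boot=1000, seed=SEED)
        rows.append({
            "comparison": name, "S_a": r.S_a, "S_u": r.S_u,
            "expected": round(r.ES_a, 1), "delta": round(r.delta, 1),
            "AD": round(r.AD, 2), "PC": round(r.PC, 1) if r.PC is not None else "",
            "p": f"{r.p_value:.2g}",
            "AD_ci95": f"({r.AD_ci95[0]:.2f}, {r.AD_ci95[1]:.2f})",
        })
        print(f"{name}: AD {r.AD:.2f}% {rows[-1]['AD_ci95']}, "
              f"PC {r.PC:.1f}%, p {r.p_value:.2g}" if r.PC is not None else name)

    agg = aggregate_burden(
        [inputs["SSC LGD vs SYN"], inputs["SSC coding CNV"]],
        n_perm=1000, n_boot=1000, seed=SEED,
    )
    rows.append({
        "comparison": "SSC LGD + coding CNV (aggregated)", "S_a": agg.S_a, "S_u": agg.S_u,
        "expected": round(agg.ES_a, 1), "delta": round(agg.delta, 1),
        "AD": round(agg.AD, 2), "PC": round(agg.PC, 1), "p": f"{agg.p_value:.2g}",
        "AD_ci95": f"({agg.AD_ci95[0]:.2f}, {agg.AD_ci95[1]:.2f})",
    })
    print(f"aggregated SSC LGD + coding CNV: AD {agg.AD:.2f}%, p {agg.p_value:.2g}")

    p_diff = compare_affected_groups(
        inputs["SSC LGD vs SYN"], inputs["AGRE LGD vs SYN"], n_perm=1000, seed=SEED
    )
    print(f"SSC vs AGRE affected (LGD differential): one-sided p = {p_diff:.3g}")

    pd.DataFrame(rows).to_csv(RESULTS / "burden.tsv", sep="\t", index=False)
    print(f"wrote {RESULTS / 'burden.tsv'}")


if __name__ == "__main__":
    main()
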