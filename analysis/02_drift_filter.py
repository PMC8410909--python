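#!/usr/bin/env python
"""Fit the cell-line drift ellipse on whole-blood children and label everyone.

Reads the simulated artifacts from 01, summarizes each child by
(power-adjusted substitution count, mean alternative allele ratio), fits the
bivariate Gaussian to whole-blood children of both collections jointly, and
classifies every child against the 99.9% ellipse. Writes
results/drift_labels.tsv and prints the per-collection exclusion rates.
"""

from collections import defaultdict
from pathlib import Path

import pandas as pd

from trioburden import (
    classify_children,
    compute_drift_stats,
    fit_drift_model,
    read_pedigree,
    read_variant_table,
)
from trioburden.synthetic_cohort import detection_probability

RESULTS = Path(__file__).resolve().parent.parent / "results"
SIM = RESULTS / "sim"


def main() -> None:
    cohort, by_child = [], defaultdict(list)
    for label in ("ssc", "agre"):
        cohort += read_pedigree(SIM / f"{label}_pedigree.tsv")
        for v in read_variant_table(SIM / f"{label}_small_variants.tsv", kind="SMALL"):
            by_child[v.child_id].append(v)

    stats = []
    for child in cohort:
        power = float(detection_probability(child.mean_coverage))
        stats.append(compute_drift_stats(by_child.get(child.child_id, []), power,
                                         child_id=child.child_id))

    wb_ids = {c.child_id for c in cohort if c.dna_source == "WB"}
    model = fit_drift_model([s for s in stats if s.child_id in wb_ids])
    labels = classify_children(model, stats)

    rows = []
    for child, s in zip(cohort, stats):
        d2 = (float(model.mahalanobis_sq([[s.adjusted_subs, s.mean_alt_ratio]])[0])
              if s.complete else float("nan"))
        rows.append({
            "child_id": s.child_id,
            "collection": child.collection,
            "dna_source": child.dna_source,
            "observed": s.observed_subs,
            "power": round(s.snv_power, 4),
            "adjusted": round(s.adjusted_subs, 2),
            "mean_ratio": round(s.mean_alt_ratio, 4) if s.complete else "",
            "mahalanobis_sq": round(d2, 3) if s.complete else "",
            "label": labels[s.child_id],
        })
    df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "drift_labels.tsv", sep="\t", index=False)

    print(f"drift ellipse threshold (Mahalanobis^2): {model.mahalanobis_sq_threshold:.4f}")
    for (coll, src), grp in df.groupby(["collection", "dna_source"]):
        drifted = (grp["label"] == "DRIFTED").sum()
        print(f"  {coll} {src}: {drifted}/{len(grp)} excluded "
              f"({100 * drifted / len(grp):.1f}%)")
    print(f"wrote {RESULTS / 'drift_labels.tsv'}")


if __name__ == "__main__":
    main()
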