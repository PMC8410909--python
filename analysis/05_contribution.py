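#!/usr/bin/env python
"""Overall de novo contribution estimates from per-class differentials.

Tallies per-class contributions to simplex autism, solves the two-risk-class
decomposition S = pLs*L + pHs*H for the low-risk contribution L, and
combines low/high-risk contributions into overall estimates two ways
(risk-class weights and registry case proportions). Writes
results/contribution.txt.
"""

from pathlib import Path

from trioburden import (
    overall_by_case_proportion,
    overall_by_risk_class,
    solve_low_risk_range,
    total_simplex_contribution,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"

# per-class contributions in simplex autism (percent of affected children);
# CNV and intronic-indel figures from this pipeline's burden estimates,
# LGD/missense/promoter from prior literature
CODING = {"coding CNV": 4.0, "LGD": 9.0, "missense": 12.0}
NONCODING = {"intronic CNV": 1.0, "intronic small indels": 5.0, "promoter": 7.0}

SIMPLEX_RANGE = (35.0, 45.0)   # overall simplex contribution with uncertainty
MULTIPLEX_RANGE = (9.0, 11.0)  # about a quarter of the simplex contribution
P_LOW_SIMPLEX = 0.6            # fraction of simplex families that are low risk
MULTIPLEX_CASES, SIMPLEX_CASES = 13_775, 65_184  # registry release counts


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    lines = []

    def emit(s: str) -> None:
        lines.append(s)
        print(s)

    emit("Per-class de novo contributions in simplex autism")
    for name, v in {**CODING, **NONCODING}.items():
        emit(f"  {name:22s} {v:4.0f}%")
    emit(f"  coding subtotal        {total_simplex_contribution(CODING):4.0f}%")
    emit(f"  non-coding subtotal    {total_simplex_contribution(NONCODING):4.0f}%")
    emit(f"  total                  {total_simplex_contribution({**CODING, **NONCODING}):4.0f}%")

    L = solve_low_risk_range(SIMPLEX_RANGE, MULTIPLEX_RANGE, pLs=P_LOW_SIMPLEX)
    emit("")
    emit(f"S (simplex) = {SIMPLEX_RANGE[0]:.0f}-{SIMPLEX_RANGE[1]:.0f}%, "
         f"H (high risk) = {MULTIPLEX_RANGE[0]:.0f}-{MULTIPLEX_RANGE[1]:.0f}%, "
         f"pLs = {P_LOW_SIMPLEX}")
    emit(f"low-risk contribution L = (S - pHs*H)/pLs = {L[0]:.1f}-{L[1]:.1f}% "
         f"(prints as {int(L[0])}-{int(L[1])}%)")

    overall_rc = overall_by_risk_class((int(L[0]), int(L[1])), MULTIPLEX_RANGE)
    emit(f"overall (half low, half high risk): {overall_rc[0]:.1f}-{overall_rc[1]:.1f}%")

    overall_cp, p = overall_by_case_proportion(
        SIMPLEX_RANGE, MULTIPLEX_RANGE, MULTIPLEX_CASES, SIMPLEX_CASES
    )
    emit(f"overall (registry case proportions, p_multiplex = {p:.4f}): "
         f"{overall_cp[0]:.1f}-{overall_cp[1]:.1f}%")

    (RESULTS / "contribution.txt").write_text("\n".join(lines) + "\n")
    print(f"wrote {RESULTS / 'contribution.txt'}")


if __name__ == "__main__":
    main()
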