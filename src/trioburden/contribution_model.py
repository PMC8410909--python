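"""Combining per-class ascertainment differentials into overall de novo
contribution estimates for high- and low-risk families.

The unified two-risk-class model holds that de novo mutation dominates
causation in low-risk families while transmission dominates in high-risk
(multiplex) families. Simplex collections mix the two, with an estimated
fraction pLs of simplex families being low risk, so the simplex contribution
S decomposes as

    S = pLs * L + pHs * H,        pHs = 1 - pLs

where L and H are the de novo contributions in low- and high-risk families.
Given S and H, L = (S - pHs * H) / pLs. Overall contributions combine L and
H (or S and H) endpoint-wise over [lo, hi] ranges, weighting either by risk
class (half of autism from each) or by the empirical proportion of cases
found in multiplex vs simplex families in a large registry.

All arithmetic is interval endpoint arithmetic at full precision; display
rounding is the caller's concern.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .cohort_io import get_logger

_log = get_logger(__name__)

Range = tuple[float, float]

__all__ = [
    "total_simplex_contribution",
    "solve_low_risk",
    "solve_low_risk_range",
    "overall_by_risk_class",
    "overall_by_case_proportion",
]


def total_simplex_contribution(class_ADs: Mapping[str, float]) -> float:
    """Sum per-class contributions (percent of affected children).

    The simple tally is valid under the assumption that the expected number
    of contributory events per child is below one, so classes rarely
    co-occur. Negative entries are warned about but included as-is.
    """
    for name, v in class_ADs.items():
        if v < 0:
            _log.warning("class %s has negative contribution %.2f%%; included as-is", name, v)
    return float(sum(class_ADs.values()))


def solve_low_risk(S: float, H: float, pLs: float = 0.6, pHs: float | None = None) -> float:
    """Solve S = pLs*L + pHs*H for the low-risk contribution L (exact)."""
    if pHs is None:
        pHs = 1.0 - pLs
    if pLs <= 0:
        raise ValueError("pLs must be positive")
    if abs(pLs + pHs - 1.0) > 1e-9:
        raise ValueError(f"pLs + pHs = {pLs + pHs}, expected 1")
    return (S - pHs * H) / pLs


def solve_low_risk_range(S: Range, H: Range, pLs: float = 0.6, pHs: float | None = None) -> Range:
    """Endpoint-wise solve: lo pairs with lo, hi with hi."""
    return (solve_low_risk(S[0], H[0], pLs, pHs), solve_low_risk(S[1], H[1], pLs, pHs))


def overall_by_risk_class(
    L: Range, H: Range, w_low: float = 0.5, w_high: float = 0.5
) -> Range:
    """Overall contribution as a risk-class weighted endpoint-wise sum."""
    if abs(w_low + w_high - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    return (w_low * L[0] + w_high * H[0], w_low * L[1] + w_high * H[1])


def overall_by_case_proportion(
    S: Range, H: Range, multiplex_cases: int, simplex_cases: int
) -> tuple[Range, float]:
    """Overall contribution weighted by the empirical multiplex case share.

    Returns the endpoint-wise combined range and p = multiplex cases /
    (multiplex + simplex) at full precision (the unrounded p is what
    reproduces the printed combined range).
    """
    total = multiplex_cases + simplex_cases
    if total <= 0 or multiplex_cases < 0 or simplex_cases < 0:
        raise ValueError("case counts must be non-negative with a positive total")
    p = multiplex_cases / total
    combined = ((1 - p) * S[0] + p * H[0], (1 - p) * S[1] + p * H[1])
    return combined, p
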