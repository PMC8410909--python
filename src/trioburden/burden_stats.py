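"""Burden statistics: expected counts, ascertainment differential (AD),
percent contributory (PC), permutation p-values and bootstrap intervals.

The comparison contrasts a *subject* variant class (e.g. LGD) in affected
children against its null expectation derived from the unaffected group,
absorbing covariates (coverage, parental age, residual cell-line drift)
through a presumed-neutral *normalization* class:

    ES_a = S_u * (N_a / N_u)            expected subject count in affected
    AD   = 100 * (S_a - ES_a) / C_a     excess per 100 affected children
    PC   = 100 * (S_a - ES_a) / S_a     excess as a fraction of observed

In CHILD_COUNT mode the normalization class is the children themselves
(every child contributes N = 1), so ES_a = S_u * (C_a / C_u).

The permutation p-value is the upper tail of a normal distribution fitted to
ADs from label permutations that keep group sizes fixed (children carry
their subject/normalization count pairs through the shuffle, and expected
counts are recomputed per permutation). Bootstrap intervals are percentile
2.5/97.5 over child-level resampling within each group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .cohort_io import get_logger

_log = get_logger(__name__)

__all__ = [
    "NormalizationMode",
    "BurdenInput",
    "BurdenResult",
    "expected_count",
    "ascertainment_differential",
    "percent_contributory",
    "burden_from_totals",
    "aggregate_from_totals",
    "permutation_p",
    "bootstrap_ci",
    "burden_test",
    "compare_affected_groups",
    "aggregate_burden",
]


class NormalizationMode(str, Enum):
    EVENT_CLASS = "EVENT_CLASS"
    CHILD_COUNT = "CHILD_COUNT"


# ---------------------------------------------------------------------------
# Point statistics (exact ratio arithmetic, no rounding)
# ---------------------------------------------------------------------------


def expected_count(S_u: float, N_a: float, N_u: float) -> float:
    """Expected subject-class count in the affected group under the null."""
    if N_u == 0:
        raise ValueError("normalization count in unaffected group is zero")
    return S_u * (N_a / N_u)


def ascertainment_differential(S_a: float, ES_a: float, C_a: int) -> float:
    """Excess subject events per 100 affected children (may be negative)."""
    if C_a == 0:
        raise ValueError("affected group has zero children")
    return 100.0 * (S_a - ES_a) / C_a


def percent_contributory(S_a: float, ES_a: float) -> float:
    """Percent of observed subject events in affected that are in excess."""
    if S_a == 0:
        raise ValueError("percent contributory undefined when no subject events observed")
    return 100.0 * (S_a - ES_a) / S_a


# ---------------------------------------------------------------------------
# Cohort-level containers
# ---------------------------------------------------------------------------


@dataclass
class BurdenInput:
    """Per-child subject/normalization counts for one affected-vs-unaffected
    comparison. In CHILD_COUNT mode the normalization arrays are all ones."""

    subject_a: np.ndarray
    subject_u: np.ndarray
    norm_a: np.ndarray
    norm_u: np.ndarray
    mode: NormalizationMode = NormalizationMode.EVENT_CLASS

    def __post_init__(self) -> None:
        self.subject_a = np.asarray(self.subject_a, dtype=np.int64)
        self.subject_u = np.asarray(self.subject_u, dtype=np.int64)
        if self.mode == NormalizationMode.CHILD_COUNT:
            self.norm_a = np.ones_like(self.subject_a)
            self.norm_u = np.ones_like(self.subject_u)
        else:
            self.norm_a = np.asarray(self.norm_a, dtype=np.int64)
            self.norm_u = np.asarray(self.norm_u, dtype=np.int64)
        if len(self.norm_a) != len(self.subject_a) or len(self.norm_u) != len(self.subject_u):
            raise ValueError("subject and normalization arrays must align per child")
        if (
            (self.subject_a < 0).any()
            or (self.subject_u < 0).any()
            or (self.norm_a < 0).any()
            or (self.norm_u < 0).any()
        ):
            raise ValueError("counts must be non-negative")
        if len(self.subject_a) == 0 or len(self.subject_u) == 0:
            raise ValueError("both groups must be non-empty")

    @classmethod
    def from_counts(
        cls,
        subject_a,
        subject_u,
        norm_a=None,
        norm_u=None,
        mode: NormalizationMode = NormalizationMode.EVENT_CLASS,
    ) -> "BurdenInput":
        if mode == NormalizationMode.CHILD_COUNT:
            norm_a = np.ones(len(subject_a))
            norm_u = np.ones(len(subject_u))
        return cls(subject_a, subject_u, norm_a, norm_u, mode)

    @property
    def C_a(self) -> int:
        return len(self.subject_a)

    @property
    def C_u(self) -> int:
        return len(self.subject_u)

    def totals(self) -> tuple[int, int, int, int]:
        return (
            int(self.subject_a.sum()),
            int(self.subject_u.sum()),
            int(self.norm_a.sum()),
            int(self.norm_u.sum()),
        )


@dataclass
class BurdenResult:
    S_a: int
    S_u: int
    N_a: int
    N_u: int
    C_a: int
    ES_a: float
    delta: float
    AD: float
    PC: float | None
    p_value: float | None = None
    AD_ci95: tuple[float, float] | None = None
    PC_ci95: tuple[float, float] | None = None
    n_permutations: int = 0
    n_bootstrap: int = 0
    seed: int | None = None


def _point_result(inp: BurdenInput) -> BurdenResult:
    S_a, S_u, N_a, N_u = inp.totals()
    ES = expected_count(S_u, N_a, N_u)
    ad = ascertainment_differential(S_a, ES, inp.C_a)
    pc = percent_contributory(S_a, ES) if S_a > 0 else None
    return BurdenResult(
        S_a=S_a, S_u=S_u, N_a=N_a, N_u=N_u, C_a=inp.C_a,
        ES_a=ES, delta=S_a - ES, AD=ad, PC=pc,
    )


# ---------------------------------------------------------------------------
# Totals-only paths for printed-table inputs
# ---------------------------------------------------------------------------


def burden_from_totals(
    S_u: int,
    S_a: int,
    N_u: int,
    N_a: int,
    C_a: int,
    C_u: int | None = None,
    mode: NormalizationMode = NormalizationMode.EVENT_CLASS,
) -> BurdenResult:
    """Point statistics from group totals, as printed in summary tables.

    In CHILD_COUNT mode ``N_u``/``N_a`` are ignored and the child counts
    ``C_u``/``C_a`` are the normalization totals.
    """
    if mode == NormalizationMode.CHILD_COUNT:
        if C_u is None:
            raise ValueError("CHILD_COUNT mode needs C_u")
        N_u, N_a = C_u, C_a
    ES = expected_count(S_u, N_a, N_u)
    ad = ascertainment_differential(S_a, ES, C_a)
    pc = percent_contributory(S_a, ES) if S_a > 0 else None
    return BurdenResult(
        S_a=S_a, S_u=S_u, N_a=N_a, N_u=N_u, C_a=C_a,
        ES_a=ES, delta=S_a - ES, AD=ad, PC=pc,
    )


def aggregate_from_totals(
    entries: Sequence[tuple[int, int, int, int, NormalizationMode]],
    C_a: int,
    C_u: int,
) -> BurdenResult:
    """Aggregate several disjoint classes from totals, each with its own
    normalization (full-precision expectations, summed before the AD).

    ``entries`` holds (S_u, S_a, N_u, N_a, mode) per class; in CHILD_COUNT
    mode the class's N values are replaced by the child counts.
    """
    S_a_sum, S_u_sum, ES_sum = 0, 0, 0.0
    for S_u, S_a, N_u, N_a, mode in entries:
        if mode == NormalizationMode.CHILD_COUNT:
            N_u, N_a = C_u, C_a
        ES_sum += expected_count(S_u, N_a, N_u)
        S_a_sum += S_a
        S_u_sum += S_u
    ad = ascertainment_differential(S_a_sum, ES_sum, C_a)
    pc = percent_contributory(S_a_sum, ES_sum) if S_a_sum > 0 else None
    return BurdenResult(
        S_a=S_a_sum, S_u=S_u_sum, N_a=0, N_u=0, C_a=C_a,
        ES_a=ES_sum, delta=S_a_sum - ES_sum, AD=ad, PC=pc,
    )


# ---------------------------------------------------------------------------
# Permutation and bootstrap
# ---------------------------------------------------------------------------


def _permutation_matrix(rng: np.random.Generator, n_perm: int, n: int) -> np.ndarray:
    return np.argsort(rng.random((n_perm, n)), axis=1)


def _permuted_ads(inp: BurdenInput, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    S_pool = np.concatenate([inp.subject_a, inp.subject_u]).astype(float)
    N_pool = np.concatenate([inp.norm_a, inp.norm_u]).astype(float)
    n, C_a = len(S_pool), inp.C_a
    idx = _permutation_matrix(rng, n_perm, n)
    aff = idx[:, :C_a]
    S_a = S_pool[aff].sum(axis=1)
    N_a = N_pool[aff].sum(axis=1)
    S_u = S_pool.sum() - S_a
    N_u = N_pool.sum() - N_a
    with np.errstate(divide="ignore", invalid="ignore"):
        ES = S_u * N_a / N_u
    return 100.0 * (S_a - ES) / C_a


def _normal_upper_tail(observed: float, null_values: np.ndarray) -> float:
    mean = float(np.mean(null_values))
    sd = float(np.std(null_values, ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        warnings.warn("degenerate permutation distribution (zero spread); p set to 1.0")
        return 1.0
    return float(sps.norm.sf(observed, loc=mean, scale=sd))


def permutation_p(
    inp: BurdenInput, n_perm: int = 1000, seed: int | np.random.Generator = 0
) -> float:
    """One-sided upper-tail p for the observed AD, from a normal fitted to
    ADs under affected/unaffected label permutation (group sizes fixed)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = _point_result(inp).AD
    return _normal_upper_tail(observed, _permuted_ads(inp, n_perm, rng))


def bootstrap_ci(
    inp: BurdenInput, n_boot: int = 1000, seed: int | np.random.Generator = 0
) -> tuple[tuple[float, float], tuple[float, float]]:
    """95% percentile bootstrap intervals for (AD, PC): children resampled
    with replacement within each group, counts travelling with the child."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    C_a, C_u = inp.C_a, inp.C_u
    ia = rng.integers(0, C_a, size=(n_boot, C_a))
    iu = rng.integers(0, C_u, size=(n_boot, C_u))
    S_a = inp.subject_a[ia].sum(axis=1).astype(float)
    N_a = inp.norm_a[ia].sum(axis=1).astype(float)
    S_u = inp.subject_u[iu].sum(axis=1).astype(float)
    N_u = inp.norm_u[iu].sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ES = S_u * N_a / N_u
        ad = 100.0 * (S_a - ES) / C_a
        pc = np.where(S_a > 0, 100.0 * (S_a - ES) / np.where(S_a > 0, S_a, 1.0), np.nan)
    ad_ci = (float(np.percentile(ad, 2.5)), float(np.percentile(ad, 97.5)))
    pc_ci = (float(np.nanpercentile(pc, 2.5)), float(np.nanpercentile(pc, 97.5)))
    return ad_ci, pc_ci


def burden_test(
    inp: BurdenInput, n_perm: int = 1000, n_boot: int = 1000, seed: int = 0
) -> BurdenResult:
    """Full burden analysis for one subject/normalization class pair.

    Permutation and bootstrap consume independent child streams spawned from
    ``seed``, so enabling one never changes the other's draws.
    """
    res = _point_result(inp)
    ss = np.random.SeedSequence(seed)
    perm_rng, boot_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    res.p_value = permutation_p(inp, n_perm, perm_rng)
    res.AD_ci95, res.PC_ci95 = bootstrap_ci(inp, n_boot, boot_rng)
    res.n_permutations = n_perm
    res.n_bootstrap = n_boot
    res.seed = seed
    return res


def compare_affected_groups(
    inp1: BurdenInput,
    inp2: BurdenInput,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """One-sided p for AD(group 1) > AD(group 2), two affected groups against
    their fixed unaffected baselines, by permuting children between the two
    affected groups (sizes fixed) and fitting a normal to the permuted
    AD differences."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = _point_result(inp1).AD - _point_result(inp2).AD
    S_pool = np.concatenate([inp1.subject_a, inp2.subject_a]).astype(float)
    N_pool = np.concatenate([inp1.norm_a, inp2.norm_a]).astype(float)
    n1 = inp1.C_a
    n = len(S_pool)
    Su1, Nu1 = float(inp1.subject_u.sum()), float(inp1.norm_u.sum())
    Su2, Nu2 = float(inp2.subject_u.sum()), float(inp2.norm_u.sum())
    idx = _permutation_matrix(rng, n_perm, n)
    g1 = idx[:, :n1]
    S1 = S_pool[g1].sum(axis=1)
    N1 = N_pool[g1].sum(axis=1)
    S2 = S_pool.sum() - S1
    N2 = N_pool.sum() - N1
    ad1 = 100.0 * (S1 - Su1 * N1 / Nu1) / n1
    ad2 = 100.0 * (S2 - Su2 * N2 / Nu2) / inp2.C_a
    return _normal_upper_tail(obs, ad1 - ad2)


def aggregate_burden(
    inputs: Sequence[BurdenInput],
    n_perm: int = 1000,
    n_boot: int = 1000,
    seed: int = 0,
) -> BurdenResult:
    """Joint burden over disjoint classes with per-class normalization.

    All inputs must describe the same children in the same order (equal group
    sizes). Expected counts are computed per class at full precision and
    summed; the permutation shuffles children once, jointly carrying every
    class's count pair; the bootstrap resamples children once per iteration.
    """
    if not inputs:
        raise ValueError("no classes to aggregate")
    C_a, C_u = inputs[0].C_a, inputs[0].C_u
    for inp in inputs[1:]:
        if inp.C_a != C_a or inp.C_u != C_u:
            raise ValueError("aggregated classes must share the same cohorts")

    per_class = [_point_result(inp) for inp in inputs]
    S_a = sum(r.S_a for r in per_class)
    S_u = sum(r.S_u for r in per_class)
    ES = sum(r.ES_a for r in per_class)
    ad_obs = ascertainment_differential(S_a, ES, C_a)
    pc_obs = percent_contributory(S_a, ES) if S_a > 0 else None

    ss = np.random.SeedSequence(seed)
    perm_rng, boot_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    n = C_a + C_u
    idx = _permutation_matrix(perm_rng, n_perm, n)
    aff = idx[:, :C_a]
    ad_perm = np.zeros(n_perm)
    for inp in inputs:
        S_pool = np.concatenate([inp.subject_a, inp.subject_u]).astype(float)
        N_pool = np.concatenate([inp.norm_a, inp.norm_u]).astype(float)
        S1 = S_pool[aff].sum(axis=1)
        N1 = N_pool[aff].sum(axis=1)
        ES_p = (S_pool.sum() - S1) * N1 / (N_pool.sum() - N1)
        ad_perm += 100.0 * (S1 - ES_p) / C_a
    p = _normal_upper_tail(ad_obs, ad_perm)

    ia = boot_rng.integers(0, C_a, size=(n_boot, C_a))
    iu = boot_rng.integers(0, C_u, size=(n_boot, C_u))
    ad_boot = np.zeros(n_boot)
    S_a_boot = np.zeros(n_boot)
    for inp in inputs:
        S1 = inp.subject_a[ia].sum(axis=1).astype(float)
        N1 = inp.norm_a[ia].sum(axis=1).astype(float)
        S0 = inp.subject_u[iu].sum(axis=1).astype(float)
        N0 = inp.norm_u[iu].sum(axis=1).astype(float)
        ad_boot += 100.0 * (S1 - S0 * N1 / N0) / C_a
        S_a_boot += S1
    ad_ci = (float(np.percentile(ad_boot, 2.5)), float(np.percentile(ad_boot, 97.5)))
    with np.errstate(divide="ignore", invalid="ignore"):
        pc_boot = ad_boot * C_a / S_a_boot
    pc_ci = (float(np.nanpercentile(pc_boot, 2.5)), float(np.nanpercentile(pc_boot, 97.5)))

    return BurdenResult(
        S_a=S_a, S_u=S_u, N_a=0, N_u=0, C_a=C_a,
        ES_a=ES, delta=S_a - ES, AD=ad_obs, PC=pc_obs,
        p_value=p, AD_ci95=ad_ci, PC_ci95=pc_ci,
        n_permutations=n_perm, n_bootstrap=n_boot, seed=seed,
    )
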