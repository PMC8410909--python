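"""Cell-line genetic drift QC: per-child statistics and the 99.9% ellipse.

DNA from cultured lymphoblastoid cell lines accumulates somatic variants
that masquerade as de novo calls, with two hallmarks: an inflated genome-wide
substitution count and alternative-allele read ratios pulled away from the
heterozygous expectation (~0.47). Each child is summarized by the pair
(power-adjusted substitution count, mean alternative allele ratio); a
bivariate Gaussian is fitted to the whole-blood children and the ellipse
containing 99.9% of its density (squared Mahalanobis distance at the
chi-square(2 df) 0.999 quantile, 13.8155) defines the pass region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .cohort_io import DeNovoVariant, get_logger

_log = get_logger(__name__)

PASS = "PASS"
DRIFTED = "DRIFTED"
INCOMPLETE = "INCOMPLETE"


@dataclass(frozen=True)
class DriftStat:
    """Drift summary for one child.

    ``adjusted_subs`` is the observed substitution count divided by the
    child's estimated detection power; ``mean_alt_ratio`` is the unweighted
    mean of per-substitution alternative allele ratios, undefined (None, stat
    incomplete) when the child has no substitutions.
    """

    child_id: str
    observed_subs: int
    snv_power: float
    adjusted_subs: float
    mean_alt_ratio: float | None

    @property
    def complete(self) -> bool:
        return self.mean_alt_ratio is not None


@dataclass(frozen=True)
class DriftModel:
    """Fitted bivariate Gaussian over (adjusted_subs, mean_alt_ratio)."""

    mean: np.ndarray
    covariance: np.ndarray
    mahalanobis_sq_threshold: float
    coverage_level: float

    def mahalanobis_sq(self, points: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(points) - self.mean
        inv = np.linalg.inv(self.covariance)
        return np.einsum("ij,jk,ik->i", d, inv, d)


def compute_drift_stats(
    variants: Iterable[DeNovoVariant], snv_power: float, child_id: str | None = None
) -> DriftStat:
    """Summarize one child's de novo substitutions for the drift filter.

    Only substitutions are used (indels are excluded). ``snv_power`` must lie
    in (0, 1]; a child with zero substitutions is flagged incomplete and is
    excluded from the Gaussian fit downstream.
    """
    if not 0.0 < snv_power <= 1.0:
        raise ValueError(f"snv_power must be in (0, 1], got {snv_power}")
    subs = [v for v in variants if v.var_type == "SUB"]
    cid = child_id if child_id is not None else (subs[0].child_id if subs else "")
    n = len(subs)
    if n == 0:
        return DriftStat(cid, 0, snv_power, 0.0, None)
    ratios = [v.alt_ratio for v in subs]
    return DriftStat(cid, n, snv_power, n / snv_power, float(np.mean(ratios)))


def fit_drift_model(
    stats_in: Sequence[DriftStat], coverage_level: float = 0.999
) -> DriftModel:
    """Fit the bivariate Gaussian to whole-blood children's drift statistics.

    Sample moments define the Gaussian; the pass ellipse is the squared
    Mahalanobis contour at the chi-square(2 df) quantile of
    ``coverage_level``. Incomplete stats are ignored; at least 10 complete
    stats are required and a singular covariance raises.
    """
    pts = np.array(
        [[s.adjusted_subs, s.mean_alt_ratio] for s in stats_in if s.complete], dtype=float
    )
    if len(pts) < 10:
        raise ValueError(f"need >= 10 complete drift stats to fit, got {len(pts)}")
    mean = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    if not np.all(np.linalg.eigvalsh(cov) > 1e-12 * max(1.0, float(np.trace(cov)))):
        raise ValueError("singular covariance: drift statistics are degenerate")
    threshold = float(stats.chi2.ppf(coverage_level, df=2))
    return DriftModel(
        mean=mean, covariance=cov, mahalanobis_sq_threshold=threshold,
        coverage_level=coverage_level,
    )


def classify_children(
    model: DriftModel, stats_in: Sequence[DriftStat]
) -> dict[str, str]:
    """Label each child PASS (inside or on the ellipse), DRIFTED, or
    INCOMPLETE (no substitutions, hence no mean allele ratio)."""
    labels: dict[str, str] = {}
    complete = [s for s in stats_in if s.complete]
    for s in stats_in:
        if not s.complete:
            labels[s.child_id] = INCOMPLETE
    if complete:
        pts = np.array([[s.adjusted_subs, s.mean_alt_ratio] for s in complete])
        d2 = model.mahalanobis_sq(pts)
        for s, dd in zip(complete, d2):
            labels[s.child_id] = PASS if dd <= model.mahalanobis_sq_threshold else DRIFTED
    return labels
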