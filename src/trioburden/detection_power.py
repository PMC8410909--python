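"""Detection-power simulation for de novo substitutions and CNVs.

Substitution power: for random positions, parents receive (depth, 0)
reference/alternative read counts and the child an alternative count drawn
from Binomial(p = 0.47, N = child depth); the resulting 2x3 count matrix is
passed through a trio genotyper and power is the detected fraction. The
genotyper here is a documented stand-in (a binomial likelihood-ratio caller
with the same filtering contract as the published multinomial genotyper);
its score scale is its own and is not numerically comparable to published
score thresholds.

CNV power: deletion-like signal is planted by transplanting a male child's
hemizygous X-chromosome read-depth bins into a random autosomal region of
the same size (the region-swap construction), then asking whether a
read-depth deletion finder recovers a call overlapping the planted region.
The finder is likewise a narrow stand-in: maximal runs of bins whose
population z-score falls below a threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps

from .cohort_io import get_logger

_log = get_logger(__name__)

__all__ = [
    "GenotyperConfig",
    "standin_genotyper",
    "snv_power",
    "PowerEstimate",
    "BinMatrix",
    "simulate_bin_matrix",
    "ZScoreDeletionFinder",
    "cnv_power_by_size",
    "constant_coverage",
    "poisson_coverage",
]


@dataclass(frozen=True)
class GenotyperConfig:
    """Thresholds of the stand-in trio genotyper.

    ``min_denovo_score`` bounds the natural-log likelihood ratio of a
    heterozygous-child/homozygous-parents trio against an all-reference trio
    under a binomial read model; ``min_consistency`` bounds the two-sided
    binomial test p-value of the child's allele ratio against
    ``alt_ratio_null``.
    """

    model: str = "STANDIN_LRT"
    alt_ratio_null: float = 0.47
    seq_error: float = 0.005
    min_denovo_score: float = 8.0
    min_consistency: float = 0.001
    min_alt_reads: int = 3


@dataclass(frozen=True)
class PowerEstimate:
    subject: str
    n_sim: int
    n_detected: int

    @property
    def power(self) -> float:
        return self.n_detected / self.n_sim if self.n_sim else 0.0


def _genotype_batch(
    child_ref: np.ndarray,
    child_alt: np.ndarray,
    mother_alt: np.ndarray,
    father_alt: np.ndarray,
    config: GenotyperConfig,
) -> np.ndarray:
    """Vectorized de novo decision over positions. Parents' reference counts
    drop out of the likelihood ratio (identical under both hypotheses)."""
    n = child_ref + child_alt
    a = child_alt
    with np.errstate(divide="ignore", invalid="ignore"):
        llr = sps.binom.logpmf(a, n, config.alt_ratio_null) - sps.binom.logpmf(
            a, n, config.seq_error
        )
        lower = sps.binom.cdf(a, n, config.alt_ratio_null)
        upper = sps.binom.sf(a - 1, n, config.alt_ratio_null)
    consistency = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    ok = (
        (a >= config.min_alt_reads)
        & (mother_alt == 0)
        & (father_alt == 0)
        & (llr >= config.min_denovo_score)
        & (consistency > config.min_consistency)
    )
    return np.where(n > 0, ok, False)


def standin_genotyper(counts: np.ndarray, config: GenotyperConfig = GenotyperConfig()) -> str:
    """Classify a single 2x3 (ref/alt x mother/father/child) count matrix.

    Returns ``"DENOVO"`` or ``"NOT"``.
    """
    counts = np.asarray(counts)
    if counts.shape != (2, 3) or (counts < 0).any():
        raise ValueError("counts must be a non-negative 2x3 (ref/alt x mo/fa/ch) matrix")
    hit = _genotype_batch(
        child_ref=np.array([counts[0, 2]]),
        child_alt=np.array([counts[1, 2]]),
        mother_alt=np.array([counts[1, 0]]),
        father_alt=np.array([counts[1, 1]]),
        config=config,
    )[0]
    return "DENOVO" if hit else "NOT"


def constant_coverage(depth: int) -> Callable:
    def sampler(rng: np.random.Generator, n: int):
        d = np.full(n, depth, dtype=np.int64)
        return d.copy(), d.copy(), d.copy()

    return sampler


def poisson_coverage(mean_depth: float) -> Callable:
    def sampler(rng: np.random.Generator, n: int):
        return (
            rng.poisson(mean_depth, n),
            rng.poisson(mean_depth, n),
            rng.poisson(mean_depth, n),
        )

    return sampler


def snv_power(
    coverage_sampler: Callable,
    config: GenotyperConfig = GenotyperConfig(),
    n_positions: int = 10000,
    seed: int = 0,
    subject: str = "trio",
) -> PowerEstimate:
    """Estimate per-trio power to detect a de novo substitution.

    ``coverage_sampler(rng, n)`` yields (mother, father, child) depths for
    ``n`` random positions. A true heterozygous de novo is simulated at each
    position (child alt ~ Binomial(0.47, depth), parents clean) and passed
    through the genotyper.
    """
    if n_positions < 100:
        warnings.warn("fewer than 100 simulated positions gives an unstable power estimate")
    rng = np.random.default_rng(seed)
    _, _, child_depth = coverage_sampler(rng, n_positions)
    child_depth = np.asarray(child_depth, dtype=np.int64)
    alt = rng.binomial(child_depth, config.alt_ratio_null)
    detected = _genotype_batch(
        child_ref=child_depth - alt,
        child_alt=alt,
        mother_alt=np.zeros(n_positions, dtype=np.int64),
        father_alt=np.zeros(n_positions, dtype=np.int64),
        config=config,
    )
    return PowerEstimate(subject=subject, n_sim=n_positions, n_detected=int(detected.sum()))


# ---------------------------------------------------------------------------
# CNV power by region swap
# ---------------------------------------------------------------------------


@dataclass
class BinMatrix:
    """Normalized read-depth bin counts for a trio population.

    ``values`` is samples x bins (row-median normalized to 1); bins are
    fixed-width and located by ``bin_chrom``/``bin_start``. ``masks`` lists
    excluded intervals (pseudoautosomal, telomeric, centromeric) per
    chromosome in bp coordinates.
    """

    values: np.ndarray
    sample_ids: list[str]
    male_child: np.ndarray  # bool per sample: a male child eligible for swaps
    bin_chrom: np.ndarray
    bin_start: np.ndarray
    bin_width: int
    masks: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("bin values must be non-negative")
        self.male_child = np.asarray(self.male_child, dtype=bool)
        self.bin_chrom = np.asarray(self.bin_chrom)
        self.bin_start = np.asarray(self.bin_start, dtype=np.int64)

    def bins_of(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.bin_chrom == chrom)

    def unmasked_bins(self, chrom: str) -> np.ndarray:
        idx = self.bins_of(chrom)
        keep = np.ones(len(idx), dtype=bool)
        for s, e in self.masks.get(chrom, []):
            starts = self.bin_start[idx]
            keep &= ~((starts < e) & (starts + self.bin_width > s))
        return idx[keep]


def simulate_bin_matrix(
    n_samples: int = 50,
    n_autosome_bins: int = 2000,
    n_x_bins: int = 500,
    mean_depth: float = 30.0,
    bin_width: int = 100,
    male_fraction: float = 0.5,
    telomere_bins: int = 10,
    seed: int = 0,
) -> BinMatrix:
    """Synthetic bin matrix: Poisson counts at ``mean_depth`` per autosomal
    bin, X bins at half depth for males (hemizygous), rows median-normalized.
    Telomeric bins at each chromosome end are masked."""
    rng = np.random.default_rng(seed)
    male = np.zeros(n_samples, dtype=bool)
    male[: int(round(n_samples * male_fraction))] = True
    lam = np.full((n_samples, n_autosome_bins + n_x_bins), mean_depth)
    lam[male, n_autosome_bins:] = mean_depth / 2.0
    counts = rng.poisson(lam).astype(float)
    med = np.median(counts[:, :n_autosome_bins], axis=1, keepdims=True)
    values = counts / np.maximum(med, 1.0)
    bin_chrom = np.array(["chr1"] * n_autosome_bins + ["chrX"] * n_x_bins)
    bin_start = np.concatenate(
        [np.arange(n_autosome_bins), np.arange(n_x_bins)]
    ) * bin_width
    masks = {
        "chr1": [
            (0, telomere_bins * bin_width),
            ((n_autosome_bins - telomere_bins) * bin_width, n_autosome_bins * bin_width),
        ],
        "chrX": [
            (0, telomere_bins * bin_width),
            ((n_x_bins - telomere_bins) * bin_width, n_x_bins * bin_width),
        ],
    }
    return BinMatrix(
        values=values,
        sample_ids=[f"s{i}" for i in range(n_samples)],
        male_child=male,
        bin_chrom=bin_chrom,
        bin_start=bin_start,
        bin_width=bin_width,
        masks=masks,
    )


@dataclass
class ZScoreDeletionFinder:
    """Stand-in read-depth deletion caller.

    Calls maximal runs of at least ``min_consecutive_bins`` bins whose
    per-bin z-score against the population column distribution is at or
    below ``-z_threshold``. Zero-variance columns carry no signal. Requires
    at least 20 samples for stable column statistics.
    """

    z_threshold: float = 4.0
    min_consecutive_bins: int = 3

    def _column_stats(self, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if values.shape[0] < 20:
            raise ValueError("need >= 20 samples for stable column statistics")
        return values.mean(axis=0), values.std(axis=0, ddof=1)

    def calls_for_sample(
        self, bins: BinMatrix, sample_index: int, values: np.ndarray | None = None
    ) -> list[tuple[str, int, int]]:
        """Candidate deletions for one sample as (chrom, first_bin, last_bin)
        global bin-index pairs (inclusive)."""
        vals = bins.values if values is None else values
        mean, sd = self._column_stats(vals)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(sd > 0, (vals[sample_index] - mean) / sd, 0.0)
        hit = z <= -self.z_threshold
        calls: list[tuple[str, int, int]] = []
        for chrom in dict.fromkeys(bins.bin_chrom.tolist()):
            idx = bins.bins_of(chrom)
            h = hit[idx]
            run_start = None
            for j, flag in enumerate(np.append(h, False)):
                if flag and run_start is None:
                    run_start = j
                elif not flag and run_start is not None:
                    if j - run_start >= self.min_consecutive_bins:
                        calls.append((chrom, int(idx[run_start]), int(idx[j - 1])))
                    run_start = None
        return calls

    def __call__(self, bins: BinMatrix) -> dict[str, list[tuple[str, int, int]]]:
        return {
            sid: self.calls_for_sample(bins, i) for i, sid in enumerate(bins.sample_ids)
        }


def cnv_power_by_size(
    bins: BinMatrix,
    sizes: Sequence[int] = tuple(range(1000, 10001, 1000)),
    finder: ZScoreDeletionFinder | None = None,
    n_sim: int = 10000,
    seed: int = 0,
    sham: bool = False,
) -> list[PowerEstimate]:
    """Power to detect planted de novo deletions of each size (bp).

    Per simulation: a random male child; a random unmasked X region of the
    requested size; a random unmasked autosomal region of the same size; the
    child's autosomal bin values over that region are replaced by his X
    values (hemizygous, so roughly half depth) and the finder is run for that
    child on the updated matrix. Detection = any finder call overlapping the
    planted region. ``sham=True`` replaces the region with its own values
    (no signal), which estimates the finder's false-call rate.
    """
    finder = finder or ZScoreDeletionFinder()
    rng = np.random.default_rng(seed)
    males = np.flatnonzero(bins.male_child)
    if len(males) == 0:
        raise ValueError("no male children in the bin matrix")
    autosomes = [c for c in dict.fromkeys(bins.bin_chrom.tolist()) if c != "chrX"]
    if "chrX" not in bins.bin_chrom or not autosomes:
        raise ValueError("bin matrix must include chrX and at least one autosome")

    out = []
    for size in sizes:
        n_bins = size // bins.bin_width
        if n_bins < 1:
            raise ValueError(f"region size {size} is below one bin width {bins.bin_width}")
        x_ok = _eligible_starts(bins, "chrX", n_bins)
        if len(x_ok) == 0:
            raise ValueError(f"no eligible X region of size {size}")
        auto_ok = {c: _eligible_starts(bins, c, n_bins) for c in autosomes}
        detected = 0
        for _ in range(n_sim):
            child = int(rng.choice(males))
            auto = autosomes[int(rng.integers(len(autosomes)))]
            a_ok = auto_ok[auto]
            a0 = int(rng.choice(a_ok))
            x0 = int(rng.choice(x_ok))
            target = np.arange(a0, a0 + n_bins)
            source = target if sham else np.arange(x0, x0 + n_bins)
            values = bins.values.copy()
            values[child, target] = values[child, source]
            calls = finder.calls_for_sample(bins, child, values=values)
            lo, hi = target[0], target[-1]
            if any(c == auto and not (e < lo or s > hi) for c, s, e in calls):
                detected += 1
        out.append(
            PowerEstimate(subject=f"size={size}", n_sim=n_sim, n_detected=detected)
        )
    return out


def _eligible_starts(bins: BinMatrix, chrom: str, n_bins: int) -> np.ndarray:
    """Global bin indices where an n_bins-long unmasked run may start."""
    idx = bins.bins_of(chrom)
    unmasked = set(bins.unmasked_bins(chrom).tolist())
    ok = []
    for j in range(len(idx) - n_bins + 1):
        window = idx[j : j + n_bins]
        if all(int(b) in unmasked for b in window):
            ok.append(int(window[0]))
    return np.array(ok, dtype=np.int64)
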