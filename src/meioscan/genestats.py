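"""Classical genetics statistics for recombination and nondisjunction assays.

Map distance in centimorgans with binomial-variance confidence intervals,
crossover density excluding transposable-element sequence, two-interval
crossover interference (coefficient of coincidence), X-nondisjunction
frequency with the inviable-class correction, percent-reduction /
percent-resolved arithmetic, and summaries plus t-tests for per-nucleus
DSB focus counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Interval",
    "IntervalCounts",
    "NdjCounts",
    "FociSample",
    "MapDistance",
    "Interference",
    "map_distance",
    "stevens_ci",
    "crossover_density",
    "interference",
    "x_ndj",
    "percent_reduction",
    "percent_resolved",
    "foci_summary",
    "one_sample_test",
]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# interval counts


@dataclass(frozen=True)
class Interval:
    name: str
    span_bp: float
    te_masked_bp: float = 0.0

    def __post_init__(self) -> None:
        if self.span_bp <= 0:
            raise ValueError("interval span must be > 0")
        if not 0 <= self.te_masked_bp <= self.span_bp:
            raise ValueError("te_masked_bp must be within [0, span]")


@dataclass
class IntervalCounts:
    """Progeny crossover-class tallies over ordered marker intervals.

    ``classes`` maps a tuple of interval names carrying a crossover in that
    progeny class (the empty tuple is the parental class; repeats denote
    multiple crossovers in one interval) to the number of progeny scored in
    the class.
    """

    intervals: list[Interval]
    classes: dict[tuple[str, ...], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = {iv.name for iv in self.intervals}
        for key, count in self.classes.items():
            if count < 0:
                raise ValueError("negative progeny tally")
            if not set(key) <= names:
                raise ValueError(f"unknown interval in class {key!r}")

    @property
    def n(self) -> int:
        return sum(self.classes.values())

    def interval(self, name: str) -> Interval:
        for iv in self.intervals:
            if iv.name == name:
                return iv
        raise KeyError(name)

    def recombinants(self, name: str) -> int:
        """Crossovers in an interval, counting single-, double- and
        triple-crossover chromosomes."""
        return sum(count * key.count(name) for key, count in self.classes.items())

    def observed_dco(self, i1: str, i2: str) -> int:
        return sum(
            count for key, count in self.classes.items() if i1 in key and i2 in key
        )


# ---------------------------------------------------------------------------
# map distance and density


@dataclass
class MapDistance:
    cM: float
    ci: tuple[float, float]
    r: int
    n: int


def stevens_ci(r: int, n: int, alpha: float = 0.05, method: str = "wald") -> tuple[float, float]:
    """Confidence interval on a map distance (cM), clamped to [0, 100].

    ``method='wald'`` is the plain normal approximation computed from the
    binomial variance of R/n. For sparse recombinant counts (roughly
    n*p < 20) the variance formula undercovers badly — r = 0 gives a
    zero-width interval — so the score interval (``method='wilson'``) is
    provided as the small-count-safe construction and is the one whose
    empirical coverage holds up across the regimes a recombination assay
    meets.
    """
    if method == "wilson":
        from scipy.stats import binomtest

        ci = binomtest(r, n).proportion_ci(confidence_level=1 - alpha, method="wilson")
        return 100 * float(ci.low), 100 * float(ci.high)
    if method != "wald":
        raise ValueError("method must be 'wald' or 'wilson'")
    p = r / n
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * math.sqrt(p * (1 - p) / n)
    return (max(0.0, 100 * (p - half)), min(100.0, 100 * (p + half)))


def map_distance(counts: IntervalCounts, interval: str, ci_method: str = "wald") -> MapDistance:
    """Genetic map distance of one interval: 100 * R / n, with 95% CI."""
    n = counts.n
    if n < 1:
        raise ValueError("no progeny scored")
    r = counts.recombinants(interval)
    return MapDistance(cM=100.0 * r / n, ci=stevens_ci(r, n, method=ci_method), r=r, n=n)


def crossover_density(cM: float, span_bp: float, te_masked_bp: float = 0.0) -> float:
    """Crossover density in cM/Mb over the TE-excluded span."""
    eff = span_bp - te_masked_bp
    if eff <= 0:
        raise ValueError("effective span must be > 0 after TE masking")
    return cM / (eff / 1e6)


# ---------------------------------------------------------------------------
# interference


@dataclass
class Interference:
    expected_dco: float
    expected_dco_rounded: int
    observed_dco: int
    coefficient_of_coincidence: float | None
    interference: float | None
    undefined: bool = False


def interference(counts: IntervalCounts, i1: str, i2: str) -> Interference:
    """Two-interval crossover interference.

    Expected double crossovers under independence are n * (R1/n) * (R2/n);
    the coefficient of coincidence is observed / expected, and interference
    is 1 - c.o.c. When the expectation is zero the coefficient is
    undefined and flagged.
    """
    n = counts.n
    if n < 1:
        raise ValueError("no progeny scored")
    counts.interval(i1), counts.interval(i2)
    r1, r2 = counts.recombinants(i1), counts.recombinants(i2)
    observed = counts.observed_dco(i1, i2)
    expected = n * (r1 / n) * (r2 / n)
    if expected == 0:
        return Interference(0.0, 0, observed, None, None, undefined=True)
    coc = observed / expected
    return Interference(expected, _round_half_up(expected), observed, coc, 1.0 - coc)


# ---------------------------------------------------------------------------
# nondisjunction


@dataclass
class NdjCounts:
    normal_progeny: int
    exceptional_females: int
    exceptional_males: int

    def __post_init__(self) -> None:
        if min(self.normal_progeny, self.exceptional_females, self.exceptional_males) < 0:
            raise ValueError("counts must be >= 0")


def x_ndj(c: NdjCounts) -> tuple[float, int]:
    """%X-NDJ with the inviable-class correction.

    Viable exceptional classes are doubled (for every viable XXY female or
    X0 male an inviable XXX or Y0 complement was produced):
    %X-NDJ = 100 * (2*exc_f + 2*exc_m) / (normal + 2*exc_f + 2*exc_m).
    """
    corrected = c.normal_progeny + 2 * c.exceptional_females + 2 * c.exceptional_males
    if corrected <= 0:
        raise ValueError("no progeny counted")
    pct = 100.0 * (2 * c.exceptional_females + 2 * c.exceptional_males) / corrected
    return pct, corrected


def ndj_comparison(a: NdjCounts, b: NdjCounts) -> tuple[float, float]:
    """Two-proportion z-test on corrected totals (approximation of the
    contingency comparison used for NDJ assays)."""
    p1, n1 = x_ndj(a)
    p2, n2 = x_ndj(b)
    x1, x2 = p1 / 100 * n1, p2 / 100 * n2
    pool = (x1 + x2) / (n1 + n2)
    se = math.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    z = (p1 / 100 - p2 / 100) / se
    return z, 2 * stats.norm.sf(abs(z))


# ---------------------------------------------------------------------------
# percent arithmetic


def percent_reduction(expected: float, observed: float) -> int:
    """100 * (1 - observed/expected), rounded half-up to an integer."""
    if expected <= 0:
        raise ValueError("expected must be > 0")
    return _round_half_up(100.0 * (1.0 - observed / expected))


def percent_resolved(mean_early: float, mean_late: float) -> int:
    """Percent of DSB foci resolved between an early and a late stage."""
    if mean_early <= 0:
        raise ValueError("mean_early must be > 0")
    return _round_half_up(100.0 * (1.0 - mean_late / mean_early))


# ---------------------------------------------------------------------------
# focus counts


@dataclass
class FociSample:
    genotype: str
    region: str  # germarium region: '2A', '2B' or '3'
    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.size and (arr < 0).any():
            raise ValueError("focus counts must be >= 0")


def one_sample_test(values, mu0: float) -> tuple[float, float]:
    """One-sample t-test: t = (mean - mu0) / (s / sqrt(n)), two-tailed p.

    Zero-variance samples are handled: p = 1 when the mean equals mu0,
    p = 0 (t = +/-inf) otherwise.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two observations")
    if np.std(x, ddof=1) == 0:
        if x.mean() == mu0:
            return 0.0, 1.0
        return math.copysign(math.inf, x.mean() - mu0), 0.0
    res = stats.ttest_1samp(x, mu0)
    return float(res.statistic), float(res.pvalue)


def _mean_ci(x: np.ndarray, alpha: float = 0.05) -> tuple[float, float, float]:
    m = float(np.mean(x))
    if x.size < 2:
        return m, m, m
    half = stats.t.ppf(1 - alpha / 2, x.size - 1) * np.std(x, ddof=1) / math.sqrt(x.size)
    return m, m - half, m + half


def foci_summary(samples: list[FociSample], equal_var: bool = False):
    """Per-group mean and 95% CI plus pairwise t-tests within each region.

    Welch's unpaired t-test by default (``equal_var=True`` for the
    classical Student variant). Identical zero-variance groups get p = 1.
    Returns (groups frame, tests frame).
    """
    grows = []
    for s in samples:
        x = np.asarray(s.counts, dtype=float)
        m, lo, hi = _mean_ci(x)
        grows.append((s.genotype, s.region, x.size, m, lo, hi))
    groups = pd.DataFrame(
        grows, columns=["genotype", "region", "n", "mean", "ci_lo", "ci_hi"]
    )
    trows = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            a, b = samples[i], samples[j]
            if a.region != b.region:
                continue
            xa = np.asarray(a.counts, dtype=float)
            xb = np.asarray(b.counts, dtype=float)
            if xa.size < 2 or xb.size < 2:
                raise ValueError("group sizes must be >= 2 for tests")
            if np.std(xa, ddof=1) == 0 and np.std(xb, ddof=1) == 0:
                t, p = (0.0, 1.0) if xa.mean() == xb.mean() else (math.inf, 0.0)
            else:
                res = stats.ttest_ind(xa, xb, equal_var=equal_var)
                t, p = float(res.statistic), float(res.pvalue)
            trows.append((a.genotype, b.genotype, a.region, t, p))
    tests = pd.DataFrame(
        trows, columns=["genotype_1", "genotype_2", "region", "t", "p"]
    )
    return groups, tests
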