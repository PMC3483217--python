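"""RNAi lifespan-screen analytics.

Two tiers of evidence are modelled.  The primary tier is a thrashing assay:
survival fractions scored on days 15, 17, 19 and 21 of adulthood, with a
gene called long- or short-lived when the relative change versus control
passes +/-10% on at least three of the four days with no day past the
threshold in the opposite direction.  The confirmation tier is longitudinal
lifespan analysis: Kaplan-Meier curves compared by the two-group log-rank
test at alpha = 0.05, with effect sizes expressed as percent change of the
mean and of the "maximum" (last-quartile mean) lifespan relative to
control.  Screen-level bookkeeping (verification frequencies, extrapolation
to untested preliminary hits, fold-improvement over genome-wide baselines,
detection rates per candidate class) lives here too.

All percentages are rounded half-up; the extrapolated verified count is
truncated (floor) before its percentage is taken.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .io import DataError

THRASHING_DAYS = (15, 17, 19, 21)

LONG, SHORT, NONE = "long", "short", "none"


def round_half_up(x: float, decimals: int = 0) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# thrashing assay

@dataclass(frozen=True)
class ThrashingRecord:
    gene: str
    survival_fraction: tuple[float, float, float, float]
    control_fraction: tuple[float, float, float, float]
    n_scored: int = 30

    def __post_init__(self) -> None:
        for tup in (self.survival_fraction, self.control_fraction):
            if len(tup) != len(THRASHING_DAYS):
                raise DataError("thrashing records need exactly 4 time points")
            if any(not (0.0 <= v <= 1.0) for v in tup):
                raise DataError("survival fractions must lie in [0, 1]")


def classify_thrashing(
    record: ThrashingRecord, threshold: float = 0.10, min_timepoints: int = 3
) -> str:
    """Call long / short / none from per-day relative survival changes.

    A day with control fraction 0 is indeterminate and excluded from the
    counts (it cannot support a relative change); if all four days are
    indeterminate the record is unusable.
    """
    n_up = n_down = n_valid = 0
    for treated, control in zip(record.survival_fraction, record.control_fraction):
        if control == 0.0:
            continue
        n_valid += 1
        change = (treated - control) / control
        if change >= threshold:
            n_up += 1
        elif change <= -threshold:
            n_down += 1
    if n_valid == 0:
        raise DataError(f"{record.gene}: all time points indeterminate (control 0)")
    if n_up >= min_timepoints and n_down == 0:
        return LONG
    if n_down >= min_timepoints and n_up == 0:
        return SHORT
    return NONE


# ---------------------------------------------------------------------------
# survival analysis

@dataclass(frozen=True)
class SurvivalDataset:
    """Per-animal observation times and death flags (False = right-censored)."""

    label: str
    times: tuple[float, ...]
    events: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.events):
            raise DataError("times and event flags must have equal length")
        if any(t <= 0 for t in self.times):
            raise DataError("observation times must be positive")

    @property
    def death_times(self) -> tuple[float, ...]:
        return tuple(t for t, e in zip(self.times, self.events) if e)

    @property
    def n_deaths(self) -> int:
        return sum(self.events)


@dataclass(frozen=True)
class KMResult:
    times: tuple[float, ...]
    survival: tuple[float, ...]
    mean: float
    median: float


def km_estimate(data: SurvivalDataset) -> KMResult:
    """Product-limit estimate with right censoring.

    The mean is the area under the survival curve up to the largest death
    time; the median is the first time the curve drops to 0.5 or below.
    Without censoring the mean equals the arithmetic mean of death times.
    """
    if data.n_deaths == 0:
        raise DataError(f"{data.label}: no death events")
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(data.times), event_observed=np.asarray(data.events, dtype=int))
    sf = kmf.survival_function_.iloc[:, 0]
    timeline = np.asarray(sf.index, dtype=float)
    surv = np.asarray(sf.values, dtype=float)
    t_max = max(data.death_times)
    # integrate the right-continuous step function over [0, t_max]
    mean = 0.0
    prev_t, prev_s = 0.0, 1.0
    for t, s in zip(timeline, surv):
        if t <= 0:
            prev_t, prev_s = 0.0, s
            continue
        upper = min(t, t_max)
        if upper > prev_t:
            mean += prev_s * (upper - prev_t)
        prev_t, prev_s = t, s
        if t >= t_max:
            break
    else:
        if t_max > prev_t:
            mean += prev_s * (t_max - prev_t)
    median = float(kmf.median_survival_time_)
    return KMResult(
        times=tuple(float(t) for t in timeline),
        survival=tuple(float(s) for s in surv),
        mean=float(mean),
        median=median,
    )


def logrank_test(a: SurvivalDataset, b: SurvivalDataset) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    if a.n_deaths == 0 or b.n_deaths == 0:
        raise DataError("both groups need at least one death for the log-rank test")
    res = _ll_logrank(
        np.asarray(a.times), np.asarray(b.times),
        event_observed_A=np.asarray(a.events, dtype=int),
        event_observed_B=np.asarray(b.events, dtype=int),
    )
    return float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class EffectMeasure:
    gene: str
    pct_delta_mean: float
    pct_delta_max: float


def _last_quartile_mean(deaths: Sequence[float]) -> float:
    n = len(deaths)
    k = math.ceil(n / 4)
    return float(np.mean(sorted(deaths)[-k:]))


def percent_changes(
    treated: SurvivalDataset, control: SurvivalDataset, gene: str = ""
) -> EffectMeasure:
    """Percent change of KM mean and of last-quartile mean lifespan.

    The last quartile ("maximum lifespan") is the mean age at death of the
    longest-lived ceil(n/4) deaths of each group.
    """
    if treated.n_deaths < 4 or control.n_deaths < 4:
        raise DataError("need >=4 deaths per group for quartile statistics")
    mean_t = km_estimate(treated).mean
    mean_c = km_estimate(control).mean
    if mean_c == 0:
        raise DataError("control mean lifespan is zero")
    max_t = _last_quartile_mean(treated.death_times)
    max_c = _last_quartile_mean(control.death_times)
    return EffectMeasure(
        gene=gene or treated.label,
        pct_delta_mean=100.0 * (mean_t - mean_c) / mean_c,
        pct_delta_max=100.0 * (max_t - max_c) / max_c,
    )


# ---------------------------------------------------------------------------
# screen bookkeeping

@dataclass(frozen=True)
class ScreenSummary:
    """Counts through the screening funnel for one candidate class."""

    genes_screened: int
    preliminary_long: int
    preliminary_short: int
    retested_long: int
    retested_short: int
    verified_long: int
    verified_short: int

    def __post_init__(self) -> None:
        for prelim, retested, verified in (
            (self.preliminary_long, self.retested_long, self.verified_long),
            (self.preliminary_short, self.retested_short, self.verified_short),
        ):
            if not (0 <= verified <= retested <= prelim <= self.genes_screened):
                raise DataError(
                    "screen funnel must satisfy verified <= retested <= "
                    "preliminary <= screened"
                )


def verification_frequency(
    summary: ScreenSummary, phenotype: str, decimals: int = 1
) -> float:
    """Verified genes as a percent of all genes screened."""
    if summary.genes_screened == 0:
        raise DataError("no genes screened")
    verified = {LONG: summary.verified_long, SHORT: summary.verified_short}[phenotype]
    return round_half_up(100.0 * verified / summary.genes_screened, decimals)


def extrapolate_verified(
    preliminary: int, retested: int, verified: int, screened: int
) -> tuple[int, float]:
    """Project the longitudinal confirmation rate onto all preliminary hits.

    Returns (floor of the projected verified count, percent of screened to
    one decimal).
    """
    if retested < 1:
        raise DataError("no retested genes to extrapolate from")
    if not (verified <= retested <= preliminary):
        raise DataError("need verified <= retested <= preliminary")
    count = math.floor(preliminary * verified / retested)
    return count, round_half_up(100.0 * count / screened, 1)


def fold_improvement(
    freq_this: float, baseline_freqs: Sequence[float]
) -> tuple[int, float]:
    """Verification frequency relative to the mean of baseline screens."""
    if not baseline_freqs or any(f <= 0 for f in baseline_freqs):
        raise DataError("baseline frequencies must be positive")
    ratio = freq_this / float(np.mean(baseline_freqs))
    return int(round_half_up(ratio)), ratio


def summarize_effects(
    effects: Iterable[EffectMeasure], direction: str, modest_cutoff: float = 10.0
) -> tuple[int, float, int]:
    """(n genes, mean %-change to 1 decimal, count of modest effects).

    Effects are deduplicated by gene id (a gene listed from both network
    sources counts once); only effects in the requested direction are
    summarized, and "modest" means |%-change of mean lifespan| strictly
    below the cutoff.
    """
    seen: dict[str, EffectMeasure] = {}
    for e in effects:
        seen.setdefault(e.gene, e)
    if direction == LONG:
        kept = [e for e in seen.values() if e.pct_delta_mean > 0]
    elif direction == SHORT:
        kept = [e for e in seen.values() if e.pct_delta_mean < 0]
    else:
        raise DataError(f"direction must be {LONG!r} or {SHORT!r}")
    if not kept:
        raise DataError("no effects in the requested direction")
    vals = [abs(e.pct_delta_mean) for e in kept]
    mean = round_half_up(float(np.mean(vals)), 1)
    n_modest = sum(1 for v in vals if v < modest_cutoff)
    return len(kept), mean, n_modest


def primary_detection_rates(
    genes_screened: int, preliminary_long: int, preliminary_short: int
) -> tuple[int, int, int]:
    """(% any phenotype, % long, % short), each rounded half-up to integer."""
    if genes_screened <= 0:
        raise DataError("no genes screened")
    any_pct = 100.0 * (preliminary_long + preliminary_short) / genes_screened
    long_pct = 100.0 * preliminary_long / genes_screened
    short_pct = 100.0 * preliminary_short / genes_screened
    return (
        int(round_half_up(any_pct)),
        int(round_half_up(long_pct)),
        int(round_half_up(short_pct)),
    )
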