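"""Synthetic fixtures with the statistical structure of the field data.

The real inputs are two years of hourly fish counts from a tidal channel,
with tidal (~12.42 h), diel (24 h), spring-neap (~14.7 / 27.6 d),
semi-annual (182 d) and annual (365 d) periodic structure, deployment gaps,
square-wave fish headings (flood plateau near 285 deg, ebb near 120 deg,
scattered headings at slack), and per-track target strengths.  This module
generates all of those from seeded configurations:

* counts are inhomogeneous Poisson with a log-linear mean built from
  sinusoidal components, optional product interactions, and optional annual
  amplitude-modulation envelopes (so tidal/diel dominance can switch
  seasonally);
* the deployment calendar is a packaged constant satisfying every printed
  property of the real one (20 gaps of 2 h to 29.5 d, separated by 1 to 57
  d of data, 582 whole days retained over the Jul 15 2013 - Jul 28 2015
  span);
* headings follow the sign of a tidal driver sinusoid with wrapped Gaussian
  noise, going uniform near the driver's zero crossings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from tidalflux.gapfill import GapLayout
from tidalflux.timeseries_io import FishTrackRecord, HourlyCountSeries
from tidalflux.tidal_model import CONSTITUENT_PERIODS_HOURS, DirectionSample

__all__ = [
    "SineComponent",
    "SeasonalEnvelope",
    "CountSimConfig",
    "DirectionSimConfig",
    "make_deployment_fixture",
    "simulate_counts",
    "count_intensity",
    "simulate_directions",
    "simulate_tracks",
    "apply_gaps",
]

HOUR = pd.Timedelta(hours=1)
ANNUAL_HOURS = 24.0 * 365.0

#: Continuous-data segment lengths (days) and gap lengths (hours) of the
#: packaged deployment calendar.  21 segments (each 1-57 d, totalling 582 d)
#: alternate with 20 gaps (each 2 h - 29.5 d, totalling 161 d) across the
#: 743-day deployment span.
_SEGMENT_DAYS = (30, 28, 25, 57, 22, 35, 1, 27, 31, 24, 38, 20, 26, 33, 19, 29, 36, 21, 23, 34, 23)
_GAP_HOURS = (2, 708, 24, 48, 12, 96, 240, 120, 360, 6, 480, 36, 144, 72, 600, 18, 300, 168, 8, 422)

DEPLOYMENT_START = pd.Timestamp("2013-07-15 00:00", tz="UTC")
DEPLOYMENT_END = pd.Timestamp("2015-07-28 00:00", tz="UTC")


@dataclass(frozen=True)
class SineComponent:
    period_hours: float
    amplitude: float  # log-scale
    phase: float = 0.0  # radians


@dataclass(frozen=True)
class SeasonalEnvelope:
    """Annual amplitude modulation: 1 - depth + depth * ((1+cos)/2)^sharpness.

    With depth 1 and a high sharpness the component is effectively switched
    on around the envelope's phase and off half a year away.
    """

    period_hours: float = ANNUAL_HOURS
    phase: float = 0.0
    depth: float = 1.0
    sharpness: float = 1.0

    def __call__(self, t_hours: np.ndarray) -> np.ndarray:
        c = 0.5 * (1.0 + np.cos(2.0 * np.pi * t_hours / self.period_hours - self.phase))
        return 1.0 - self.depth + self.depth * c**self.sharpness


@dataclass
class CountSimConfig:
    span: tuple[pd.Timestamp, pd.Timestamp] = (DEPLOYMENT_START, DEPLOYMENT_END)
    baseline_log_mean: float = np.log(20.0)
    components: tuple[SineComponent, ...] = (
        SineComponent(CONSTITUENT_PERIODS_HOURS["M2"], 0.6),
        SineComponent(24.0, 0.5),
        SineComponent(14.7 * 24.0, 0.3),
        SineComponent(27.6 * 24.0, 0.2),
        SineComponent(182.0 * 24.0, 0.4),
        SineComponent(365.0 * 24.0, 0.7),
    )
    interactions: tuple[tuple[float, float, float], ...] = ()  # (period_a, period_b, amplitude)
    seasonal_modulators: tuple[SeasonalEnvelope | None, ...] | None = None
    overdispersion: float | None = None  # negative-binomial k; None = Poisson
    seed: int = 0


@dataclass
class DirectionSimConfig:
    span: tuple[pd.Timestamp, pd.Timestamp] = (
        pd.Timestamp("2014-08-01 00:00", tz="UTC"),
        pd.Timestamp("2014-08-31 00:00", tz="UTC"),
    )
    flood_heading: float = 285.0
    ebb_heading: float = 120.0
    heading_noise_sd: float = 15.0  # degrees, wrapped Gaussian
    slack_scatter_halfwidth_minutes: float = 20.0
    samples_per_hour: float = 12.0
    driver: tuple[SineComponent, ...] = (
        SineComponent(CONSTITUENT_PERIODS_HOURS["M2"], 1.0),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.flood_heading == self.ebb_heading:
            raise ValueError("flood and ebb headings must differ")
        if self.heading_noise_sd < 0:
            raise ValueError("heading noise sd must be non-negative")


def make_deployment_fixture() -> tuple[tuple[pd.Timestamp, pd.Timestamp], GapLayout]:
    """The packaged deployment span and gap calendar.

    Exact gap positions of the real deployment were never published; this
    constant layout satisfies every printed property (gap count, duration
    and separation ranges, whole days retained).
    """
    gaps = []
    t = DEPLOYMENT_START
    for seg_days, gap_hours in zip(_SEGMENT_DAYS, _GAP_HOURS):
        t = t + pd.Timedelta(days=seg_days)
        gaps.append((t, t + pd.Timedelta(hours=gap_hours)))
        t = gaps[-1][1]
    t = t + pd.Timedelta(days=_SEGMENT_DAYS[-1])
    assert t == DEPLOYMENT_END
    return (DEPLOYMENT_START, DEPLOYMENT_END), GapLayout(tuple(gaps))


def count_intensity(config: CountSimConfig) -> tuple[pd.DatetimeIndex, np.ndarray]:
    """Hourly expected-count curve mu_t implied by a count configuration."""
    start, end = pd.Timestamp(config.span[0]), pd.Timestamp(config.span[1])
    n = int((end - start) / HOUR)
    times = pd.date_range(start, periods=n, freq="h")
    t_h = np.arange(n, dtype=float)
    log_mu = np.full(n, config.baseline_log_mean)
    mods = config.seasonal_modulators or (None,) * len(config.components)
    if len(mods) != len(config.components):
        raise ValueError("seasonal_modulators must align with components")
    comps = []
    for comp, mod in zip(config.components, mods):
        c = comp.amplitude * np.sin(2.0 * np.pi * t_h / comp.period_hours + comp.phase)
        if mod is not None:
            c = c * mod(t_h)
        comps.append((comp.period_hours, c))
        log_mu += c
    for period_a, period_b, amp in config.interactions:
        sa = np.sin(2.0 * np.pi * t_h / period_a)
        sb = np.sin(2.0 * np.pi * t_h / period_b)
        log_mu += amp * sa * sb
    if np.any(log_mu > 20.0):
        raise ValueError("log-mean exceeds overflow guard of 20")
    return times, np.exp(log_mu)


def simulate_counts(config: CountSimConfig) -> HourlyCountSeries:
    """Draw hourly counts from the configured inhomogeneous count model.

    Counts are independent Poisson (or negative binomial when an
    overdispersion parameter is set) with the log-linear mean of
    :func:`count_intensity`.  Bit-reproducible under a fixed seed.
    """
    times, mu = count_intensity(config)
    rng = np.random.default_rng(config.seed)
    if config.overdispersion is None:
        values = rng.poisson(mu).astype(float)
    else:
        k = config.overdispersion
        if k <= 0:
            raise ValueError("overdispersion k must be positive")
        values = rng.negative_binomial(k, k / (k + mu)).astype(float)
    return HourlyCountSeries.from_observations(times[0], values)


def simulate_directions(
    config: DirectionSimConfig,
) -> tuple[list[DirectionSample], list[tuple[pd.Timestamp, str]]]:
    """Square-wave heading samples driven by a tidal sinusoid.

    Headings sit on the flood or ebb plateau according to the driver's sign,
    with wrapped Gaussian noise; within the scatter half-width of a true
    zero crossing they are uniform on [0, 360).  Returns the samples and the
    true crossing times ("low_slack" at rising crossings).
    """
    start, end = pd.Timestamp(config.span[0]), pd.Timestamp(config.span[1])
    span_h = (end - start) / HOUR
    rng = np.random.default_rng(config.seed)
    n = int(round(span_h * config.samples_per_hour))
    t_h = np.sort(rng.uniform(0.0, span_h, size=n))

    def driver(t):
        out = 0.0
        for comp in config.driver:
            out = out + comp.amplitude * np.sin(
                2.0 * np.pi * np.asarray(t) / comp.period_hours + comp.phase
            )
        return out

    # true zero crossings of the driver, by scan + root refinement
    step = min(c.period_hours for c in config.driver) / 64.0
    grid = np.arange(0.0, span_h + step, step)
    fg = driver(grid)
    crossings: list[tuple[float, bool]] = []
    for i in range(len(grid) - 1):
        if fg[i] == 0.0:
            crossings.append((grid[i], fg[i + 1] > 0))
        elif fg[i] * fg[i + 1] < 0:
            r = brentq(lambda t: float(driver(t)), grid[i], grid[i + 1], xtol=1e-7)
            crossings.append((r, fg[i + 1] > fg[i]))
    cross_t = np.array([c[0] for c in crossings])

    halfwidth_h = config.slack_scatter_halfwidth_minutes / 60.0
    d = driver(t_h)
    headings = np.where(d > 0, config.flood_heading, config.ebb_heading).astype(float)
    if config.heading_noise_sd > 0:
        headings = headings + rng.normal(0.0, config.heading_noise_sd, size=n)
    if len(cross_t) and halfwidth_h > 0:
        dist = np.min(np.abs(t_h[:, None] - cross_t[None, :]), axis=1)
        in_slack = dist <= halfwidth_h
        headings[in_slack] = rng.uniform(0.0, 360.0, size=int(in_slack.sum()))
    headings = headings % 360.0
    samples = [
        DirectionSample(time=start + pd.Timedelta(hours=float(t)), heading=float(h))
        for t, h in zip(t_h, headings)
    ]
    truth = [
        (start + pd.Timedelta(hours=float(t)), "low_slack" if rising else "high_slack")
        for t, rising in crossings
    ]
    return samples, truth


def simulate_tracks(
    hourly_intensity: Sequence[float],
    start: pd.Timestamp,
    ts_median: float = -45.1,
    ts_iqr: tuple[float, float] = (-46.5, -43.4),
    seed: int = 0,
) -> list[FishTrackRecord]:
    """Per-track fixtures: Poisson counts per hour, Gaussian target strengths.

    Track timestamps are uniform within their hour; mean TS is Gaussian with
    median ``ts_median`` and quartiles matching ``ts_iqr`` (a Gaussian's
    quartiles sit 0.6745 sd either side of the median).
    """
    mu = np.asarray(hourly_intensity, dtype=float)
    if np.any(mu < 0):
        raise ValueError("intensities must be non-negative")
    start = pd.Timestamp(start)
    rng = np.random.default_rng(seed)
    z75 = 0.6744897501960817
    sd = (ts_iqr[1] - ts_iqr[0]) / (2.0 * z75)
    tracks: list[FishTrackRecord] = []
    counts = rng.poisson(mu)
    k = 0
    for h, c in enumerate(counts):
        if c == 0:
            continue
        offsets = np.sort(rng.uniform(0.0, 1.0, size=c))
        ts = rng.normal(ts_median, sd, size=c)
        n_targets = 5 + rng.poisson(5.0, size=c)
        durations = rng.exponential(2.0, size=c)
        for o, t, nt, du in zip(offsets, ts, n_targets, durations):
            tracks.append(
                FishTrackRecord(
                    track_id=f"trk{k:07d}",
                    mean_time=start + pd.Timedelta(hours=h + float(o)),
                    duration=float(du),
                    n_targets=int(nt),
                    mean_ts=float(t),
                    heading=None,
                )
            )
            k += 1
    return tracks


def simulate_benchmark_series(
    span: tuple[pd.Timestamp, pd.Timestamp] = (DEPLOYMENT_START, DEPLOYMENT_END),
    baseline: float = 120.0,
    components: Sequence[tuple[float, float, float]] = (
        (0.5 * 24.0, 40.0, 0.0),
        (1.0 * 24.0, 30.0, 1.0),
        (14.7 * 24.0, 10.0, 2.0),
        (182.0 * 24.0, 30.0, 3.0),
        (365.0 * 24.0, 70.0, 4.0),
    ),
    noise_sd: float = 8.0,
    seed: int = 0,
) -> HourlyCountSeries:
    """Additive sinusoid-plus-noise series for gap-fill method comparison.

    A known-composition benchmark: midline plus count-scale sinusoids at the
    tidal, diel, spring-neap, semi-annual and annual periods, plus Gaussian
    white noise, clipped at zero.  Unlike the Poisson pipeline generator,
    this series lies in the harmonic gap model's own family, which is what a
    fill-method comparison needs — a truth the best method can actually
    recover.  Each element is (period_hours, amplitude, phase_radians).
    """
    start, end = pd.Timestamp(span[0]), pd.Timestamp(span[1])
    n = int((end - start) / HOUR)
    t_h = np.arange(n, dtype=float)
    y = np.full(n, float(baseline))
    for period_h, amp, phase in components:
        y += amp * np.sin(2.0 * np.pi * t_h / period_h + phase)
    rng = np.random.default_rng(seed)
    y += rng.normal(0.0, noise_sd, size=n)
    return HourlyCountSeries.from_observations(start, np.clip(y, 0.0, None))


def apply_gaps(series: HourlyCountSeries, layout: GapLayout) -> HourlyCountSeries:
    """Mask the layout's gap hours as missing, leaving all else untouched."""
    return layout.mask(series)
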