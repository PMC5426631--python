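"""Tidal stage from fish swimming directions.

In a narrow tidal channel, tracked fish move almost exclusively with the
current except briefly at slack water, so fish heading is a proxy for
current direction.  A harmonic model — midline plus sine/cosine terms at up
to 15 standard tidal constituent periods — is least-squares fitted to the
(unwrapped) headings; sinusoid peaks mark peak flood, troughs peak ebb, and
midline crossings mark slack tides.  Rising crossings (ebb plateau to flood
plateau) are labeled low slack by default, falling crossings high slack.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from tidalflux.gapfill import HarmonicModel, _design_matrix, _hours_since

__all__ = [
    "CONSTITUENT_PERIODS_HOURS",
    "DirectionSample",
    "ConstituentSet",
    "TidalStageSeries",
    "constituent_periods",
    "unwrap_headings",
    "fit_tidal_model",
    "predict_direction",
    "slack_times",
    "stage_series",
]

HOUR = pd.Timedelta(hours=1)

#: Standard astronomical periods (hours) of the supported constituents.
CONSTITUENT_PERIODS_HOURS: dict[str, float] = {
    "M2": 12.4206,
    "S2": 12.0000,
    "N2": 12.6583,
    "K2": 11.9672,
    "K1": 23.9345,
    "O1": 25.8193,
    "P1": 24.0659,
    "Q1": 26.8684,
    "M4": 6.2103,
    "L2": 12.1916,
    "NU2": 12.6260,
    "2N2": 12.9054,
    "MF": 327.8599,
    "MM": 661.3112,
    "SSA": 4382.9052,
}

#: The ten short-period constituents used in short-term channel modeling,
#: plus the five longer-period ones relevant to a multi-year record.
SHORT_TERM_TEN = ("M2", "K1", "K2", "N2", "S2", "O1", "L2", "M4", "NU2", "2N2")
LONG_TERM_FIVE = ("P1", "Q1", "MF", "MM", "SSA")
ALL_CONSTITUENTS = SHORT_TERM_TEN + LONG_TERM_FIVE


@dataclass(frozen=True)
class DirectionSample:
    time: pd.Timestamp
    heading: float  # degrees [0, 360)

    def __post_init__(self) -> None:
        if not (0.0 <= self.heading < 360.0):
            raise ValueError(f"heading must lie in [0, 360), got {self.heading}")


@dataclass(frozen=True)
class ConstituentSet:
    names: tuple[str, ...]
    periods: tuple[float, ...]  # hours

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("constituent names must be unique")
        if len(self.names) != len(self.periods):
            raise ValueError("names and periods must have equal length")


@dataclass
class TidalStageSeries:
    """Per-time tidal stage labels and half-cycle phase."""

    times: pd.DatetimeIndex
    stage: np.ndarray  # of {"flood", "ebb", "high_slack", "low_slack"}
    phase: np.ndarray  # fraction of current half-cycle elapsed, [0, 1)

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.stage) == len(self.phase)):
            raise ValueError("times, stage and phase must have equal length")
        bad = set(self.stage) - {"flood", "ebb", "high_slack", "low_slack"}
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_utc": self.times, "stage": self.stage, "phase": self.phase})


def constituent_periods(names: Sequence[str]) -> ConstituentSet:
    """Look up standard periods (hours) for the requested constituents."""
    unknown = [n for n in names if n not in CONSTITUENT_PERIODS_HOURS]
    if unknown:
        raise ValueError(
            f"unknown constituent(s): {', '.join(unknown)}; "
            f"supported: {', '.join(sorted(CONSTITUENT_PERIODS_HOURS))}"
        )
    return ConstituentSet(tuple(names), tuple(CONSTITUENT_PERIODS_HOURS[n] for n in names))


def unwrap_headings(headings: np.ndarray, seam: float = 20.0) -> np.ndarray:
    """Re-express circular headings on a continuous axis with the seam moved.

    Values are mapped into [seam, seam + 360); taking the result mod 360
    reproduces the inputs.  Choose the seam away from both flow plateaus so
    neither straddles the discontinuity.
    """
    h = np.asarray(headings, dtype=float)
    return (h - seam) % 360.0 + seam


def fit_tidal_model(
    samples: Sequence[DirectionSample],
    constituents: ConstituentSet,
    seam: float = 20.0,
) -> HarmonicModel:
    """Least-squares harmonic fit of unwrapped fish headings.

    The design holds a midline column plus sine and cosine columns at every
    constituent period; rank deficiency (a record too short to separate some
    constituent) raises an error naming the offending constituents.
    """
    if len(samples) < 2 * (2 * len(constituents.names) + 1):
        raise ValueError("too few direction samples for the requested constituents")
    times = pd.DatetimeIndex([s.time for s in samples])
    span_h = (times.max() - times.min()) / HOUR
    if span_h < 2 * CONSTITUENT_PERIODS_HOURS["M2"]:
        raise ValueError("direction record must span at least two M2 cycles")
    epoch = times.min().floor("h")
    t_h = _hours_since(times, epoch)
    y = unwrap_headings(np.array([s.heading for s in samples]), seam=seam)
    X = _design_matrix(t_h, constituents.periods)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        offenders = [
            name
            for name, p in zip(constituents.names, constituents.periods)
            if p > span_h / 2.0
        ] or list(constituents.names)
        raise ValueError(
            "rank-deficient tidal design; record cannot separate constituent(s): "
            + ", ".join(offenders)
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    k = len(constituents.periods)
    resid = y - X @ beta
    dof = max(len(y) - X.shape[1], 1)
    return HarmonicModel(
        periods=np.array(constituents.periods, dtype=float),
        coef_sin=beta[1 : 1 + k],
        coef_cos=beta[1 + k :],
        midline=float(beta[0]),
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
        epoch=epoch,
        fit_window=(times.min(), times.max()),
    )


def predict_direction(model: HarmonicModel, times) -> np.ndarray:
    """Model heading at the given times, re-wrapped to [0, 360) degrees."""
    return np.asarray(model.predict(times)) % 360.0


def slack_times(
    model: HarmonicModel,
    span: tuple[pd.Timestamp, pd.Timestamp],
    rising_is_low: bool = True,
    scan_step_minutes: float = 5.0,
) -> list[tuple[pd.Timestamp, str]]:
    """All midline crossings of the fitted sinusoid within ``span``.

    Crossings are bracketed on a fine scan grid and refined by root finding
    to better than one second.  Rising crossings are low slack under the
    default convention (the ebb-to-flood turnover happens at low water);
    pass ``rising_is_low=False`` for sites with the opposite phasing.
    """
    if len(model.periods) == 0:
        raise ValueError("constant (midline-only) model has no slack crossings")
    t0 = _hours_float(span[0], model.epoch)
    t1 = _hours_float(span[1], model.epoch)
    if t1 <= t0:
        raise ValueError("span end must be after span start")
    step = scan_step_minutes / 60.0
    grid = np.arange(t0, t1 + step, step)
    f = model.predict_hours(grid) - model.midline
    out: list[tuple[pd.Timestamp, str]] = []
    func = lambda t: float(model.predict_hours(np.array([t]))[0] - model.midline)
    for i in range(len(grid) - 1):
        a, b = f[i], f[i + 1]
        if a == 0.0:
            root = grid[i]
            rising = b > 0
        elif a * b < 0:
            root = brentq(func, grid[i], grid[i + 1], xtol=1.0 / 7200.0)  # < 1 s
            rising = b > a
        else:
            continue
        label = ("low_slack" if rising else "high_slack") if rising_is_low else (
            "high_slack" if rising else "low_slack"
        )
        t_root = model.epoch + pd.Timedelta(hours=float(root))
        if t_root >= span[0] and t_root < span[1]:
            if out and abs((t_root - out[-1][0]) / HOUR) < step / 2:
                continue  # same crossing caught twice at a grid point
            out.append((t_root, label))
    return out


def stage_series(
    model: HarmonicModel,
    times: pd.DatetimeIndex,
    slack_halfwidth_minutes: float = 30.0,
) -> TidalStageSeries:
    """Label each time flood/ebb/slack and locate it within its half-cycle.

    Times within the half-width of a midline crossing take that crossing's
    slack label; otherwise the label is flood above the midline and ebb
    below.  Phase is the elapsed fraction between the bounding crossings.
    """
    times = pd.DatetimeIndex(times)
    if len(times) == 0:
        return TidalStageSeries(times, np.array([], dtype=object), np.array([]))
    longest = float(np.max(model.periods))
    pad = pd.Timedelta(hours=longest)
    crossings = slack_times(model, (times.min() - pad, times.max() + pad))
    if len(crossings) < 2:
        raise ValueError("model produces too few midline crossings to define stages")
    cross_t = np.array([_hours_float(t, model.epoch) for t, _ in crossings])
    cross_lab = [lab for _, lab in crossings]
    t_h = _hours_since(times, model.epoch)
    pred = model.predict_hours(t_h)
    halfwidth_h = slack_halfwidth_minutes / 60.0
    stage = np.empty(len(times), dtype=object)
    phase = np.zeros(len(times))
    idx = np.searchsorted(cross_t, t_h, side="right") - 1
    for i, (t, p) in enumerate(zip(t_h, pred)):
        j = idx[i]
        j = min(max(j, 0), len(cross_t) - 2)
        lo, hi = cross_t[j], cross_t[j + 1]
        phase[i] = (t - lo) / (hi - lo) if hi > lo else 0.0
        d_near = min(abs(t - lo), abs(hi - t))
        if d_near <= halfwidth_h:
            k = j if abs(t - lo) <= abs(hi - t) else j + 1
            stage[i] = cross_lab[k]
        else:
            stage[i] = "flood" if p > model.midline else "ebb"
    phase = np.clip(phase, 0.0, np.nextafter(1.0, 0.0))
    return TidalStageSeries(times, stage, phase)


def _hours_float(t: pd.Timestamp, epoch: pd.Timestamp) -> float:
    return (pd.Timestamp(t) - epoch) / HOUR
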