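"""Flow-through (pull-mode) respirometry trace processing.

Converts raw excurrent gas-fraction recordings into whole-animal oxygen
consumption, extracts the resting metabolic rate (RMR) as the lowest 30-s
mean in the pre-stimulus search window, and quantifies the metabolic
response to an acute acoustic stressor as peak and integrated elevation over
the resting level in the minute after each alarm.

Oxygen consumption is recovered by mass balance for a pull system in which
the *excurrent* flow is metered and both O2 and CO2 are measured downstream
of the chamber:

    VO2 = FR_dry * [(FiO2 - FeO2) - FeO2 * (FeCO2 - FiCO2)] / (1 - FeO2)

with the metered flow dry-corrected via FR_dry = flow * (BP - WVP) / BP.
This is the exact N2-conserving balance (no respiratory-quotient assumption
needed when both gases are measured).  If CO2 is unavailable a fixed RQ can
be assumed instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "RespTrace",
    "VO2Series",
    "MetabolicSummary",
    "CorruptTraceError",
    "compute_vo2",
    "correct_baseline",
    "extract_rmr",
    "mass_correct",
    "stress_response",
    "summarize_session",
]

STANDARD_BP_KPA = 101.325


class CorruptTraceError(ValueError):
    """Trace violates a physical invariant (bad fractions, no baseline...)."""


@dataclass
class RespTrace:
    """One respirometry recording.

    All arrays share a common length; ``t`` is seconds since recording start
    and must be strictly increasing.  ``channel`` flags each sample as
    ``"baseline"`` (empty reference channel) or ``"test"`` (animal chamber).
    ``events`` holds alarm onset times in seconds.
    """

    t: np.ndarray
    FeO2: np.ndarray
    FeCO2: np.ndarray | None
    FiO2: float
    FiCO2: float
    flow: np.ndarray  # ml/min, wet excurrent
    channel: np.ndarray  # "baseline" | "test"
    events: tuple[float, ...] = ()
    WVP: np.ndarray | float = 0.0  # kPa
    BP: float = STANDARD_BP_KPA
    name: str = "trace"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.FeO2 = np.asarray(self.FeO2, dtype=float)
        if self.FeCO2 is not None:
            self.FeCO2 = np.asarray(self.FeCO2, dtype=float)
        self.flow = np.broadcast_to(np.asarray(self.flow, dtype=float), self.t.shape).copy()
        self.channel = np.asarray(self.channel)
        if np.any(np.diff(self.t) <= 0):
            raise CorruptTraceError(f"{self.name}: time vector not strictly increasing")
        if np.any((self.FeO2 <= 0) | (self.FeO2 >= 1)):
            raise CorruptTraceError(f"{self.name}: FeO2 outside (0, 1)")
        if np.any(self.flow <= 0):
            raise CorruptTraceError(f"{self.name}: non-positive flow")
        self.events = tuple(sorted(self.events))

    # -- I/O ---------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Plain CSV-ready long table, one row per sample."""
        event = np.zeros(len(self.t), dtype=int)
        for e in self.events:
            event[np.searchsorted(self.t, e)] = 1
        wvp = np.broadcast_to(np.asarray(self.WVP, dtype=float), self.t.shape)
        return pd.DataFrame(
            {
                "t_seconds": self.t,
                "FiO2": self.FiO2,
                "FeO2": self.FeO2,
                "FiCO2": self.FiCO2,
                "FeCO2": self.FeCO2 if self.FeCO2 is not None else np.nan,
                "WVP_kPa": wvp,
                "flow_ml_min": self.flow,
                "channel": self.channel,
                "event": event,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, name: str = "trace", bp: float = STANDARD_BP_KPA) -> "RespTrace":
        events = tuple(df.loc[df["event"] == 1, "t_seconds"].to_numpy(dtype=float))
        feco2 = df["FeCO2"].to_numpy(dtype=float)
        return cls(
            t=df["t_seconds"].to_numpy(dtype=float),
            FeO2=df["FeO2"].to_numpy(dtype=float),
            FeCO2=None if np.all(np.isnan(feco2)) else feco2,
            FiO2=float(df["FiO2"].iloc[0]),
            FiCO2=float(df["FiCO2"].iloc[0]),
            flow=df["flow_ml_min"].to_numpy(dtype=float),
            channel=df["channel"].to_numpy(),
            events=events,
            WVP=df["WVP_kPa"].to_numpy(dtype=float),
            BP=bp,
            name=name,
        )


@dataclass
class VO2Series:
    """Whole-animal oxygen consumption, ml O2 / h, on the test-channel samples."""

    t: np.ndarray
    vo2: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.vo2 = np.asarray(self.vo2, dtype=float)
        if not np.all(np.isfinite(self.vo2)):
            raise CorruptTraceError("non-finite VO2 values")


@dataclass
class MetabolicSummary:
    """Per-session metabolic statistics.

    ``rmr`` is the Kleiber mass-corrected rate rmr_raw / mass^0.75; the two
    stress statistics are percentage elevations over resting (ratio - 1, in
    %), averaged over the alarms used.
    """

    rmr_raw: float  # ml O2 / h
    rmr: float  # ml O2 / h / g^0.75
    stress_max: float | None  # %
    stress_integral: float | None  # %
    n_alarms_used: int
    body_mass: float  # g
    log: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------


def correct_baseline(trace: RespTrace) -> RespTrace:
    """Remove instrument drift using the empty-channel baseline segment(s).

    The mean excurrent fraction over each baseline segment is taken as the
    instrument's reading of incurrent air; the offset (segment mean minus the
    nominal incurrent fraction) is subtracted from the whole record.  With
    two or more baseline segments the offset is interpolated linearly in time
    between segment midpoints and held constant beyond the outermost ones.
    """
    is_base = trace.channel == "baseline"
    if not np.any(is_base):
        raise CorruptTraceError(f"{trace.name}: no baseline samples to correct against")
    # contiguous baseline segments
    idx = np.flatnonzero(is_base)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    segments = np.split(idx, breaks + 1)

    def _offset(values: np.ndarray, incurrent: float) -> np.ndarray:
        mids = np.array([trace.t[s].mean() for s in segments])
        offs = np.array([values[s].mean() - incurrent for s in segments])
        if len(segments) == 1:
            return np.full_like(values, offs[0])
        return np.interp(trace.t, mids, offs)

    new_feo2 = trace.FeO2 - _offset(trace.FeO2, trace.FiO2)
    new_feco2 = None
    if trace.FeCO2 is not None:
        new_feco2 = trace.FeCO2 - _offset(trace.FeCO2, trace.FiCO2)
    return replace(trace, FeO2=new_feo2, FeCO2=new_feco2)


def compute_vo2(
    trace: RespTrace,
    rq_assumption: float | None = None,
    use_co2: bool = True,
    negative_tolerance: float = 5.0,
) -> VO2Series:
    """Per-sample oxygen consumption on the test channel.

    Uses the two-gas pull-system balance when CO2 is present and
    ``use_co2``; otherwise a fixed respiratory quotient ``rq_assumption``
    must be supplied and the single-gas form
    FR*(FiO2-FeO2)/(1-FiO2*(1-RQ)) is used.  Baseline-channel samples are
    excluded from the returned series.  A warning reports the count of
    negative values beyond ``negative_tolerance`` ml/h.
    """
    mask = trace.channel == "test"
    if not np.any(mask):
        raise CorruptTraceError(f"{trace.name}: no test-channel samples")
    wvp = np.broadcast_to(np.asarray(trace.WVP, dtype=float), trace.t.shape)
    fr_dry = trace.flow * (trace.BP - wvp) / trace.BP  # ml/min
    feo2 = trace.FeO2[mask]
    denom = 1.0 - feo2
    if np.any(denom <= 0):
        raise CorruptTraceError(f"{trace.name}: FeO2 >= 1 makes the balance singular")
    if use_co2 and trace.FeCO2 is not None:
        dco2 = trace.FeCO2[mask] - trace.FiCO2
        vo2_min = fr_dry[mask] * ((trace.FiO2 - feo2) - feo2 * dco2) / denom
    else:
        if rq_assumption is None:
            raise ValueError(
                f"{trace.name}: CO2 channel unavailable; supply rq_assumption"
            )
        vo2_min = fr_dry[mask] * (trace.FiO2 - feo2) / (1.0 - trace.FiO2 * (1.0 - rq_assumption))
    vo2 = vo2_min * 60.0  # ml/h
    n_neg = int(np.sum(vo2 < -negative_tolerance))
    if n_neg:
        warnings.warn(
            f"{trace.name}: {n_neg} VO2 samples below -{negative_tolerance} ml/h",
            stacklevel=2,
        )
    return VO2Series(t=trace.t[mask], vo2=vo2)


def _window_means(t: np.ndarray, x: np.ndarray, span: float) -> tuple[np.ndarray, np.ndarray]:
    """Mean of x over every window [t_i, t_i + span] fully inside the record."""
    csum = np.concatenate([[0.0], np.cumsum(x)])
    ends = np.searchsorted(t, t + span, side="right")
    valid = t + span <= t[-1] + 1e-9
    starts = np.arange(len(t))[valid]
    ends = ends[valid]
    means = (csum[ends] - csum[starts]) / (ends - starts)
    return t[starts], means


def extract_rmr(
    vo2: VO2Series,
    events: tuple[float, ...],
    discard_minutes: float = 10.0,
    window_seconds: float = 30.0,
    search_minutes: float = 10.0,
) -> float:
    """Resting metabolic rate: lowest ``window_seconds`` mean in the search span.

    The search span is the last ``search_minutes`` before the first alarm,
    intersected with the data after the equilibration discard (the first
    ``discard_minutes`` of test-channel data).  Windows slide one sample at a
    time; ties break to the earliest window.
    """
    t0 = vo2.t[0]
    lo = t0 + discard_minutes * 60.0
    hi = min(events) if events else vo2.t[-1]
    lo = max(lo, hi - search_minutes * 60.0)
    mask = (vo2.t >= lo) & (vo2.t <= hi)
    tt, xx = vo2.t[mask], vo2.vo2[mask]
    if len(tt) < 2 or tt[-1] - tt[0] < window_seconds:
        raise CorruptTraceError(
            f"insufficient pre-alarm data: {0 if len(tt) == 0 else tt[-1] - tt[0]:.0f} s "
            f"available in [{lo:.0f}, {hi:.0f}], need {window_seconds:.0f} s"
        )
    _, means = _window_means(tt, xx, window_seconds)
    return float(means.min())


def mass_correct(rmr_raw: float, mass: float) -> float:
    """Kleiber correction: rmr_raw / mass^0.75 (ml O2 / h / g^0.75)."""
    if not mass > 0:
        raise ValueError(f"body mass must be positive, got {mass!r}")
    return rmr_raw / mass**0.75


def stress_response(
    vo2: VO2Series,
    alarm_t: float,
    rmr_resting: float,
    window_seconds: float = 60.0,
) -> tuple[float, float]:
    """Peak and integrated metabolic elevation after one alarm.

    Returns ``(stress_max, stress_integral)`` in percent over resting:
    stress_max = (max VO2 in [alarm, alarm+window] / resting - 1) * 100 and
    stress_integral = (trapezoidal mean VO2 over the window / resting - 1) * 100.
    The window is closed on both sides so the response at the stimulus
    instant counts toward the peak.
    """
    if not rmr_resting > 0:
        raise ValueError(f"rmr_resting must be positive, got {rmr_resting!r}")
    mask = (vo2.t >= alarm_t - 1e-9) & (vo2.t <= alarm_t + window_seconds + 1e-9)
    tt, xx = vo2.t[mask], vo2.vo2[mask]
    if len(tt) < 2 or tt[-1] - alarm_t < window_seconds - 1e-9:
        avail = 0.0 if len(tt) == 0 else tt[-1] - alarm_t
        raise CorruptTraceError(
            f"post-alarm window truncated: {avail:.0f} of {window_seconds:.0f} s available"
        )
    smax = (xx.max() / rmr_resting - 1.0) * 100.0
    integral = np.trapezoid(xx, tt) / (rmr_resting * (tt[-1] - tt[0])) - 1.0
    return float(smax), float(integral * 100.0)


def summarize_session(
    trace: RespTrace,
    mass: float,
    rq_assumption: float | None = None,
    use_co2: bool = True,
    max_alarms: int = 2,
    discard_minutes: float = 10.0,
    window_seconds: float = 30.0,
    search_minutes: float = 10.0,
    stress_window_seconds: float = 60.0,
) -> MetabolicSummary:
    """Full per-session processing chain.

    Baseline-corrects, computes VO2, extracts RMR before the first alarm,
    mass-corrects it, and averages the stress statistics over up to
    ``max_alarms`` alarms (the study repeats the stimulus once, so two).
    With no alarms the stress fields are None and RMR uses the whole
    post-discard record.
    """
    corrected = correct_baseline(trace)
    vo2 = compute_vo2(corrected, rq_assumption=rq_assumption, use_co2=use_co2)
    rmr_raw = extract_rmr(
        vo2,
        trace.events,
        discard_minutes=discard_minutes,
        window_seconds=window_seconds,
        search_minutes=search_minutes,
    )
    rmr = mass_correct(rmr_raw, mass)
    alarms = trace.events[:max_alarms]
    maxes, integrals, used = [], [], 0
    for alarm in alarms:
        try:
            smax, sint = stress_response(vo2, alarm, rmr_raw, stress_window_seconds)
        except CorruptTraceError:
            continue
        maxes.append(smax)
        integrals.append(sint)
        used += 1
    return MetabolicSummary(
        rmr_raw=rmr_raw,
        rmr=rmr,
        stress_max=float(np.mean(maxes)) if used else None,
        stress_integral=float(np.mean(integrals)) if used else None,
        n_alarms_used=used,
        body_mass=mass,
        log={
            "n_alarms_available": len(trace.events),
            "discard_minutes": discard_minutes,
            "window_seconds": window_seconds,
            "search_minutes": search_minutes,
        },
    )
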