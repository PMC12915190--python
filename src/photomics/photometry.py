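"""Dual-channel fiber-photometry analysis.

The pipeline: fit the isosbestic control channel to the signal channel
(ordinary least squares), compute the fractional fluorescence change
``dff = (signal - fitted_control) / fitted_control``, z-score it over the
whole trace (population SD, denominator N), extract peri-event windows
around annotated behavioral bout onsets, detect transients by a
baseline-mean + k*SD threshold with an absolute amplitude floor, and
quantify each transient's peak, area under the curve and single-exponential
decay time constant.

Conventions
-----------
* Times are seconds; behavioral intervals are half-open ``[onset, offset)``.
* ``dff`` is a dimensionless ratio: the default amplitude floor 0.02
  corresponds to 2% dF/F.
* Baseline statistics default to the whole trace; an iterative-exclusion
  mode (two rounds of dropping super-threshold samples) is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    DataError,
    DegenerateFitError,
    EmptyResultError,
    ParameterError,
)

__all__ = [
    "PhotometryRecording",
    "ControlFit",
    "CorrectedTrace",
    "ZScoredTrace",
    "BoutAnnotation",
    "PeriEventMatrix",
    "EventDetectionParams",
    "TransientEvent",
    "EventSummary",
    "fit_control_channel",
    "compute_dff",
    "zscore_trace",
    "extract_peri_event",
    "mean_peri_event_z",
    "detect_events",
    "fit_decay_tau",
    "segment_auc",
    "summarize_events",
]

BOUT_LABELS = ("struggle", "immobility")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class PhotometryRecording:
    """Uniformly sampled dual-channel recording.

    ``f_signal`` is the activity-dependent 470 nm channel, ``f_control`` the
    isosbestic 410 nm channel, both in arbitrary fluorescence units.
    """

    time: np.ndarray
    f_signal: np.ndarray
    f_control: np.ndarray
    sampling_rate: float
    label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.f_signal = np.asarray(self.f_signal, dtype=float)
        self.f_control = np.asarray(self.f_control, dtype=float)
        n = len(self.time)
        if n < 2:
            raise DataError("recording needs at least 2 samples")
        if len(self.f_signal) != n or len(self.f_control) != n:
            raise DataError(
                f"channel lengths differ: time={n}, "
                f"f470={len(self.f_signal)}, f410={len(self.f_control)}"
            )
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be > 0")
        dt = np.diff(self.time)
        expected = 1.0 / self.sampling_rate
        bad = np.nonzero(np.abs(dt - expected) > 1e-6 * expected)[0]
        if bad.size:
            i = int(bad[0])
            raise DataError(
                f"time axis not uniform at 1/sampling_rate: step {i}->"
                f"{i + 1} is {dt[i]:.9g} s, expected {expected:.9g} s"
            )

    @property
    def n_samples(self) -> int:
        return len(self.time)

    @property
    def duration(self) -> float:
        """Session duration in seconds (n_samples / sampling_rate)."""
        return self.n_samples / self.sampling_rate


@dataclass
class ControlFit:
    """OLS fit of the signal channel on the control channel."""

    intercept: float
    slope: float
    fitted: np.ndarray
    residual_rms: float


@dataclass
class CorrectedTrace:
    """Motion/bleach-corrected fractional fluorescence change (dff)."""

    dff: np.ndarray
    time: np.ndarray
    sampling_rate: float


@dataclass
class ZScoredTrace:
    """Whole-trace z-scored dff: z = (dff - mean) / sd, denominator-N sd."""

    z: np.ndarray
    mean_used: float
    sd_used: float
    time: np.ndarray
    sampling_rate: float


@dataclass
class BoutAnnotation:
    """Labeled behavioral intervals, half-open seconds, non-overlapping."""

    intervals: list[tuple[float, float, str]]
    session_duration: float

    def __post_init__(self) -> None:
        ivs = sorted(self.intervals, key=lambda iv: iv[0])
        prev_off = 0.0
        for onset, offset, lab in ivs:
            if onset >= offset:
                raise DataError(f"bout onset {onset} >= offset {offset}")
            if lab not in BOUT_LABELS:
                raise DataError(f"unknown bout label {lab!r}")
            if onset < prev_off - 1e-9:
                raise DataError(f"overlapping bouts at onset {onset}")
            if offset > self.session_duration + 1e-9:
                raise DataError(
                    f"bout offset {offset} exceeds session duration "
                    f"{self.session_duration}"
                )
            prev_off = offset
        self.intervals = ivs

    def onsets(self, label: str) -> list[float]:
        return [on for on, _, lab in self.intervals if lab == label]


@dataclass
class PeriEventMatrix:
    """Trials x timepoints matrix aligned to bout onsets (relative time 0)."""

    window_pre: float
    window_post: float
    values: np.ndarray
    align_times: np.ndarray
    relative_time: np.ndarray
    n_dropped: int = 0

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]


@dataclass
class EventDetectionParams:
    """Threshold-detection parameters.

    ``k_sd`` multiplies the baseline SD; ``amplitude_floor`` is an absolute
    dff floor on the event peak (0.02 = 2% dF/F). Events whose gap is below
    ``min_separation`` seconds are merged.
    """

    k_sd: float = 3.0
    amplitude_floor: float = 0.02
    min_separation: float = 0.5
    baseline_mode: Literal["whole_trace", "iterative_exclusion"] = "whole_trace"

    def __post_init__(self) -> None:
        if self.k_sd <= 0:
            raise ParameterError("k_sd must be > 0")
        if self.amplitude_floor < 0:
            raise ParameterError("amplitude_floor must be >= 0")
        if self.min_separation < 0:
            raise ParameterError("min_separation must be >= 0")
        if self.baseline_mode not in ("whole_trace", "iterative_exclusion"):
            raise ParameterError(
                f"unknown baseline_mode {self.baseline_mode!r}"
            )


@dataclass
class TransientEvent:
    """One detected transient. ``decay_tau``/``fit_r2`` are None on fit failure."""

    onset_t: float
    peak_t: float
    end_t: float
    peak_amp: float
    auc: float
    decay_tau: float | None
    fit_r2: float | None


@dataclass
class EventSummary:
    n_events: int
    frequency: float
    mean_auc: float | None
    mean_tau: float | None
    session_minutes: float


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def fit_control_channel(rec: PhotometryRecording) -> ControlFit:
    """OLS-fit the control channel to the signal channel.

    Minimizes ``sum((f_signal - a - b * f_control)**2)`` over the whole
    recording and returns the fitted series ``a + b * f_control``.

    Raises
    ------
    DataError
        If either channel contains NaN.
    DegenerateFitError
        If the control channel is constant (zero variance).
    """
    x = rec.f_control
    y = rec.f_signal
    if np.isnan(x).any() or np.isnan(y).any():
        raise DataError("NaN values in recording channels")
    xvar = np.var(x)
    if xvar == 0:
        raise DegenerateFitError(
            "control channel is constant; cannot fit control model"
        )
    b = float(np.cov(x, y, bias=True)[0, 1] / xvar)
    a = float(np.mean(y) - b * np.mean(x))
    fitted = a + b * x
    rms = float(np.sqrt(np.mean((y - fitted) ** 2)))
    return ControlFit(intercept=a, slope=b, fitted=fitted, residual_rms=rms)


def compute_dff(rec: PhotometryRecording, fit: ControlFit) -> CorrectedTrace:
    """dff[i] = (f_signal[i] - fitted[i]) / fitted[i].

    Raises :class:`DataError` listing offending indices if any fitted value
    is non-positive.
    """
    fitted = np.asarray(fit.fitted, dtype=float)
    if len(fitted) != rec.n_samples:
        raise DataError("fit length does not match recording length")
    bad = np.nonzero(fitted <= 0)[0]
    if bad.size:
        shown = ", ".join(map(str, bad[:10]))
        more = "..." if bad.size > 10 else ""
        raise DataError(
            f"fitted control <= 0 at {bad.size} sample(s): indices {shown}{more}"
        )
    dff = (rec.f_signal - fitted) / fitted
    return CorrectedTrace(dff=dff, time=rec.time.copy(),
                          sampling_rate=rec.sampling_rate)


def zscore_trace(trace: CorrectedTrace) -> ZScoredTrace:
    """Z-score the dff trace: z = (dff - mean) / sd with denominator-N sd."""
    dff = trace.dff
    if len(dff) < 2:
        raise DataError("trace too short to z-score")
    mean = float(np.mean(dff))
    sd = float(np.std(dff))  # population form, denominator N
    if sd == 0:
        raise DegenerateFitError("constant dff trace: zero SD, cannot z-score")
    return ZScoredTrace(z=(dff - mean) / sd, mean_used=mean, sd_used=sd,
                        time=trace.time.copy(),
                        sampling_rate=trace.sampling_rate)


def extract_peri_event(
    z: ZScoredTrace | CorrectedTrace,
    bouts: BoutAnnotation,
    label: str = "struggle",
    window_pre: float = 2.0,
    window_post: float = 6.0,
) -> PeriEventMatrix:
    """Extract windows of the trace aligned to bout onsets of ``label``.

    Each qualifying onset yields one row covering ``[-window_pre,
    +window_post]`` around the onset, ``round((pre+post)*fs) + 1`` samples.
    Onsets whose window would leave the recording are dropped and counted
    in ``n_dropped`` rather than padded.

    Raises :class:`EmptyResultError` when no onset qualifies.
    """
    if label not in BOUT_LABELS:
        raise ParameterError(f"unknown bout label {label!r}")
    if window_pre < 0 or window_post <= 0:
        raise ParameterError("windows must satisfy pre >= 0, post > 0")
    values = z.z if isinstance(z, ZScoredTrace) else z.dff
    fs = z.sampling_rate
    n = len(values)
    n_pre = int(round(window_pre * fs))
    n_post = int(round(window_post * fs))
    rows, align = [], []
    dropped = 0
    onsets = bouts.onsets(label)
    for onset in onsets:
        i0 = int(round(onset * fs))
        if i0 - n_pre < 0 or i0 + n_post > n - 1:
            dropped += 1
            continue
        rows.append(values[i0 - n_pre:i0 + n_post + 1])
        align.append(onset)
    if not rows:
        raise EmptyResultError(
            f"no {label!r} bout fits the [{-window_pre:g}, {window_post:g}] s "
            f"window ({len(onsets)} candidate(s), {dropped} dropped)",
            n_candidates=len(onsets),
            n_dropped=dropped,
        )
    rel_t = (np.arange(-n_pre, n_post + 1)) / fs
    return PeriEventMatrix(
        window_pre=window_pre,
        window_post=window_post,
        values=np.vstack(rows),
        align_times=np.asarray(align),
        relative_time=rel_t,
        n_dropped=dropped,
    )


def mean_peri_event_z(
    m: PeriEventMatrix, from_t: float = 0.0, to_t: float = 6.0
) -> tuple[np.ndarray, float]:
    """Per-trial means over ``relative_time`` in ``[from_t, to_t]`` and
    their grand mean."""
    if from_t >= to_t:
        raise ParameterError("from_t must be < to_t")
    if from_t < -m.window_pre - 1e-9 or to_t > m.window_post + 1e-9:
        raise ParameterError(
            f"sub-window [{from_t}, {to_t}] outside "
            f"[-{m.window_pre}, {m.window_post}]"
        )
    mask = (m.relative_time >= from_t - 1e-9) & (m.relative_time <= to_t + 1e-9)
    if not mask.any():
        raise ParameterError("sub-window contains no samples")
    per_trial = m.values[:, mask].mean(axis=1)
    return per_trial, float(per_trial.mean())


def _baseline_stats(
    dff: np.ndarray, params: EventDetectionParams
) -> tuple[float, float]:
    mean = float(np.mean(dff))
    sd = float(np.std(dff))
    if params.baseline_mode == "whole_trace":
        if sd == 0:
            raise DegenerateFitError("zero baseline SD on whole trace")
        return mean, sd
    # iterative_exclusion: re-estimate twice after dropping super-threshold
    # samples; a tiny SD guard keeps constant traces error-free (0 events).
    for _ in range(2):
        sd_g = max(sd, 1e-12)
        keep = dff <= mean + params.k_sd * sd_g
        if not keep.any():
            break
        mean = float(np.mean(dff[keep]))
        sd = float(np.std(dff[keep]))
    return mean, max(sd, 1e-12)


def segment_auc(y: np.ndarray, dt: float, baseline: float = 0.0) -> float:
    """Trapezoidal integral of ``y - baseline`` over a segment, floored at 0."""
    if len(y) < 2:
        return 0.0
    return max(float(np.trapezoid(np.asarray(y, float) - baseline, dx=dt)), 0.0)


def fit_decay_tau(
    segment: Sequence[float], sampling_rate: float
) -> tuple[float | None, float | None]:
    """Fit ``y(t) = A * exp(-t / tau) + C`` to a decay segment.

    The segment starts at the event peak (t = 0). tau is initialized from
    the time-to-half-peak divided by ln 2, A from the peak-to-tail height
    and C from the segment tail; tau > 0 is enforced by bounds. Returns
    ``(None, None)`` for segments shorter than 5 samples or failed fits —
    failure is a flag, not an exception.
    """
    y = np.asarray(segment, dtype=float)
    if len(y) < 5 or sampling_rate <= 0:
        return None, None
    t = np.arange(len(y)) / sampling_rate
    c0 = float(np.mean(y[-max(3, len(y) // 10):]))
    a0 = float(y[0] - c0)
    if a0 <= 0:
        a0 = max(float(np.ptp(y)), 1e-12)
    half = c0 + a0 / 2.0
    below = np.nonzero(y <= half)[0]
    t_half = t[below[0]] if below.size else t[-1] / 2.0
    tau0 = max(t_half / np.log(2.0), 1.0 / sampling_rate)

    def model(tt, a, tau, c):
        return a * np.exp(-tt / tau) + c

    try:
        popt, _ = curve_fit(
            model,
            t,
            y,
            p0=[a0, tau0, c0],
            bounds=([0.0, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=2000,
        )
    except (RuntimeError, ValueError):
        return None, None
    resid = y - model(t, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return float(popt[1]), r2


def detect_events(
    trace: CorrectedTrace, params: EventDetectionParams | None = None
) -> list[TransientEvent]:
    """Threshold-based transient detection.

    Threshold ``T = baseline_mean + k_sd * baseline_SD``; an event is a
    maximal run of samples with ``dff > T`` whose peak also reaches
    ``amplitude_floor``. Runs separated by less than ``min_separation``
    seconds are merged before metrics are computed. Per event: onset = first
    crossing above T, end = first return below T (or trace end), AUC =
    trapezoidal integral of ``dff - baseline_mean`` over [onset, end]
    (floored at 0), decay tau from a bounded single-exponential fit of the
    peak-to-end segment.
    """
    if params is None:
        params = EventDetectionParams()
    dff = np.asarray(trace.dff, dtype=float)
    if not np.isfinite(dff).all():
        raise DataError("non-finite values in dff trace")
    fs = trace.sampling_rate
    mean, sd = _baseline_stats(dff, params)
    thr = mean + params.k_sd * sd

    above = dff > thr
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    stops = list(np.nonzero(edges == -1)[0] + 1)  # first index back below T
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(len(dff) - 1)  # runs off the end of the trace

    # merge runs whose gap is shorter than min_separation
    gap = int(round(params.min_separation * fs))
    merged: list[tuple[int, int]] = []
    for s, e in zip(starts, stops):
        if merged and s - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))

    events: list[TransientEvent] = []
    dt = 1.0 / fs
    for s, e in merged:
        peak = s + int(np.argmax(dff[s:e + 1]))
        amp = float(dff[peak])
        if amp < params.amplitude_floor:
            continue
        auc = segment_auc(dff[s:e + 1], dt, baseline=mean)
        tau, r2 = fit_decay_tau(dff[peak:e + 1], fs)
        events.append(
            TransientEvent(
                onset_t=float(trace.time[s]),
                peak_t=float(trace.time[peak]),
                end_t=float(trace.time[e]),
                peak_amp=amp,
                auc=auc,
                decay_tau=tau,
                fit_r2=r2,
            )
        )
    return events


def summarize_events(
    events: list[TransientEvent], session_duration: float
) -> EventSummary:
    """Event frequency (events/min) and mean AUC / decay tau.

    Means are taken over events with valid values; with zero events the
    frequency is 0 and the means are None.
    """
    if session_duration <= 0:
        raise ParameterError("session_duration must be > 0")
    minutes = session_duration / 60.0
    n = len(events)
    taus = [ev.decay_tau for ev in events if ev.decay_tau is not None]
    aucs = [ev.auc for ev in events]
    return EventSummary(
        n_events=n,
        frequency=n / minutes,
        mean_auc=float(np.mean(aucs)) if aucs else None,
        mean_tau=float(np.mean(taus)) if taus else None,
        session_minutes=minutes,
    )
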