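"""Per-trial landing metrics from force-plate traces.

Given a bilateral vertical force recording of one drop landing, this module
detects ground contact, extracts the peak ground-reaction force normalised
to body weight (GRF/BW), measures the impact-absorption time (duration for
which the total force exceeds the supported weight), integrates the landing
impulse, and averages repeated trials of one condition while preserving each
trial's force impulse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ForceTrace",
    "LandingMetrics",
    "total_force",
    "detect_contact",
    "peak_grf_bw",
    "absorption_time",
    "impulse",
    "quiet_stance_bw",
    "moving_average",
    "landing_phase",
    "extract_metrics",
    "average_trials",
    "NoContactError",
]

#: default contact threshold as a fraction of the supported weight
CONTACT_THRESHOLD_FRAC = 0.05
#: minimum time the force must stay above threshold to count as contact, s
CONTACT_SUSTAIN_S = 0.010
#: margin appended after the last downward weight crossing when delimiting
#: the landing phase for impulse integration, s
LANDING_SETTLE_MARGIN_S = 0.2


class ValidationError(ValueError):
    pass


class NoContactError(RuntimeError):
    """The force never exceeds the contact threshold."""


@dataclass(frozen=True)
class ForceTrace:
    """Uniformly sampled bilateral vertical force signal for one trial."""

    time_s: np.ndarray
    fz_left_n: np.ndarray
    fz_right_n: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        left = np.asarray(self.fz_left_n, dtype=float)
        right = np.asarray(self.fz_right_n, dtype=float)
        if not (len(t) == len(left) == len(right)):
            raise ValidationError(
                f"channel length mismatch: time={len(t)}, left={len(left)}, "
                f"right={len(right)}"
            )
        if len(t) < 2:
            raise ValidationError("trace must contain at least 2 samples")
        dt = np.diff(t)
        if dt.min() <= 0 or (dt.max() - dt.min()) > 1e-9:
            raise ValidationError("time grid must be strictly increasing and uniform")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "fz_left_n", left)
        object.__setattr__(self, "fz_right_n", right)

    @property
    def fs_hz(self) -> float:
        return 1.0 / (self.time_s[1] - self.time_s[0])

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass
class LandingMetrics:
    """Scalar overload metrics derived from one trial (or averaged profile)."""

    peak_grf_bw: float
    t_abs_s: float
    impulse_ns: float
    contact_index: int
    bw_n: float
    warnings: list[str] = field(default_factory=list)


def total_force(trace: ForceTrace) -> np.ndarray:
    """Sum of the two plate channels on the trace's grid."""
    return trace.fz_left_n + trace.fz_right_n


def detect_contact(
    force: np.ndarray,
    bw_n: float,
    threshold_frac: float = CONTACT_THRESHOLD_FRAC,
    fs_hz: float | None = None,
    sustain_s: float = CONTACT_SUSTAIN_S,
) -> int:
    """First sample index of ground contact.

    Contact is the first index where the force exceeds
    ``threshold_frac * bw_n`` and stays above it for at least ``sustain_s``
    (10 ms by default), which rejects isolated noise spikes during flight.
    ``fs_hz`` is required to express the sustain window in samples; if not
    given, a single supra-threshold sample suffices.
    """
    if bw_n <= 0:
        raise ValidationError(f"bw_n must be positive, got {bw_n}")
    force = np.asarray(force, dtype=float)
    thr = threshold_frac * bw_n
    above = force > thr
    if not above.any():
        raise NoContactError(
            f"force never exceeds the contact threshold {thr:.1f} N"
        )
    need = 1 if fs_hz is None else max(1, int(round(sustain_s * fs_hz)))
    if need == 1:
        return int(np.argmax(above))
    # run lengths of consecutive supra-threshold samples
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(idx) - 1]))
    for s, e in zip(starts, ends):
        if idx[e] - idx[s] + 1 >= need:
            return int(idx[s])
    raise NoContactError(
        f"force exceeds {thr:.1f} N only in bursts shorter than {sustain_s * 1e3:.0f} ms"
    )


def peak_grf_bw(force: np.ndarray, bw_n: float, contact_index: int = 0) -> float:
    """Maximum post-contact force as a multiple of ``bw_n``."""
    if bw_n <= 0:
        raise ValidationError(f"bw_n must be positive, got {bw_n}")
    force = np.asarray(force, dtype=float)
    return float(force[contact_index:].max() / bw_n)


def _interp_crossing(t0: float, t1: float, f0: float, f1: float, level: float) -> float:
    """Time at which the segment (t0,f0)-(t1,f1) crosses ``level``."""
    if f1 == f0:
        return t0
    return t0 + (level - f0) / (f1 - f0) * (t1 - t0)


def _supra_interval(
    time_s: np.ndarray, force: np.ndarray, level: float, contact_index: int
) -> tuple[float, float] | None:
    """Boundaries of the post-contact supra-``level`` run containing the
    global post-contact maximum, with linearly interpolated crossings.

    Returns None when the force never exceeds ``level`` after contact.
    """
    f = force[contact_index:]
    t = time_s[contact_index:]
    above = f > level
    if not above.any():
        return None
    peak = int(np.argmax(f))
    if not above[peak]:  # peak exactly at level: degenerate, no supra run at peak
        return None
    # walk out from the peak to the run boundaries
    start = peak
    while start > 0 and above[start - 1]:
        start -= 1
    end = peak
    last = len(f) - 1
    while end < last and above[end + 1]:
        end += 1
    t_on = (
        _interp_crossing(t[start - 1], t[start], f[start - 1], f[start], level)
        if start > 0
        else t[start]
    )
    t_off = (
        _interp_crossing(t[end], t[end + 1], f[end], f[end + 1], level)
        if end < last
        else t[end]
    )
    return float(t_on), float(t_off)


def absorption_time(
    force: np.ndarray,
    bw_n: float,
    contact_index: int = 0,
    time_s: np.ndarray | None = None,
    fs_hz: float | None = None,
    warn_sink: list[str] | None = None,
) -> float:
    """Impact-absorption time: duration of the supra-weight landing interval.

    The interval is the first contiguous post-contact run on which the total
    force exceeds ``bw_n`` *and* which contains the global post-contact
    maximum; secondary bumps before or after the main impact are ignored.
    Crossing times are refined by linear interpolation between the bracketing
    samples, so the resolution is finer than one sample period.

    Returns 0.0 (recording a warning) when the force never exceeds the weight.
    """
    if bw_n <= 0:
        raise ValidationError(f"bw_n must be positive, got {bw_n}")
    force = np.asarray(force, dtype=float)
    if time_s is None:
        if fs_hz is None:
            raise ValidationError("either time_s or fs_hz is required")
        time_s = np.arange(len(force)) / fs_hz
    bounds = _supra_interval(np.asarray(time_s, float), force, bw_n, contact_index)
    if bounds is None:
        msg = "force never exceeds 1 BW after contact; t_abs set to 0"
        if warn_sink is not None:
            warn_sink.append(msg)
        else:
            warnings.warn(msg, stacklevel=2)
        return 0.0
    return bounds[1] - bounds[0]


def impulse(
    force: np.ndarray,
    time_s: np.ndarray | None = None,
    window: tuple[int, int] | None = None,
    fs_hz: float | None = None,
) -> float:
    """Trapezoidal integral of the force over ``window`` (N·s).

    ``window`` is an inclusive index range; the whole series by default.
    """
    force = np.asarray(force, dtype=float)
    if time_s is None:
        if fs_hz is None:
            raise ValidationError("either time_s or fs_hz is required")
        time_s = np.arange(len(force)) / fs_hz
    time_s = np.asarray(time_s, dtype=float)
    if window is not None:
        lo, hi = window
        if lo < 0 or hi >= len(force) or hi <= lo:
            raise ValidationError(f"empty or out-of-range window {window!r}")
        force = force[lo : hi + 1]
        time_s = time_s[lo : hi + 1]
    if len(force) < 2:
        raise ValidationError("window must span at least 2 samples")
    return float(np.trapezoid(force, time_s))


def quiet_stance_bw(trace: ForceTrace, window_s: float = 0.3) -> float:
    """Estimate the supported weight from the quiet-stance plateau.

    Median of the trailing ``window_s`` of the total force — an alternative
    to mass-table × g when the recording ends in stable standing.  With
    protective gear worn this estimates body *plus* gear weight.
    """
    f = total_force(trace)
    n = max(1, int(round(window_s * trace.fs_hz)))
    return float(np.median(f[-n:]))


def moving_average(force: np.ndarray, fs_hz: float, window_s: float = 0.005) -> np.ndarray:
    """Centered moving-average denoise (optional; no filtering by default).

    Width ``window_s`` (default 5 ms); edges use a shrinking window so the
    output length matches the input.
    """
    force = np.asarray(force, dtype=float)
    k = max(1, int(round(window_s * fs_hz)))
    if k <= 1:
        return force.copy()
    kernel = np.ones(k) / k
    out = np.convolve(force, kernel, mode="same")
    # fix shrinking-window edges (convolve zero-pads)
    norm = np.convolve(np.ones_like(force), kernel, mode="same")
    return out / norm


def landing_phase(
    trace: ForceTrace,
    bw_n: float,
    settle_margin_s: float = LANDING_SETTLE_MARGIN_S,
) -> tuple[int, int]:
    """Inclusive sample range of the landing phase of a trial.

    Runs from ground contact to the last downward crossing of the weight
    level plus a settle margin (0.2 s by default), clipped to the trace end.
    This window delimits the impulse integral used by trial averaging.
    """
    f = total_force(trace)
    c = detect_contact(f, bw_n, fs_hz=trace.fs_hz)
    after = f[c:]
    above = after > bw_n
    if above.any():
        last_above = int(np.flatnonzero(above)[-1])
        end = c + last_above
    else:
        end = len(f) - 1
    end = min(len(f) - 1, end + int(round(settle_margin_s * trace.fs_hz)))
    if end <= c:
        end = len(f) - 1
    return c, end


def extract_metrics(
    trace: ForceTrace,
    bw_n: float,
    threshold_n: float | None = None,
) -> LandingMetrics:
    """All per-trial overload metrics in one pass.

    ``bw_n`` normalises the peak force (GRF/BW); ``threshold_n`` is the
    weight level delimiting the absorption interval and landing phase, and
    defaults to ``bw_n``.  The two differ when protective gear is worn but
    the overload is expressed relative to body-only weight.
    """
    if threshold_n is None:
        threshold_n = bw_n
    f = total_force(trace)
    warns: list[str] = []
    c = detect_contact(f, threshold_n, fs_hz=trace.fs_hz)
    peak = peak_grf_bw(f, bw_n, c)
    t_abs = absorption_time(
        f, threshold_n, c, time_s=trace.time_s, warn_sink=warns
    )
    lo, hi = landing_phase(trace, threshold_n)
    imp = impulse(f, time_s=trace.time_s, window=(lo, hi))
    return LandingMetrics(
        peak_grf_bw=peak,
        t_abs_s=t_abs,
        impulse_ns=imp,
        contact_index=c,
        bw_n=bw_n,
        warnings=warns,
    )


def _resample_phase(
    time_s: np.ndarray, force: np.ndarray, n_out: int
) -> np.ndarray:
    """Linearly time-rescale a landing-phase segment onto ``n_out`` samples."""
    x_old = np.linspace(0.0, 1.0, len(force))
    x_new = np.linspace(0.0, 1.0, n_out)
    return np.interp(x_new, x_old, force)


def average_trials(
    traces: list[ForceTrace],
    bw_n: float,
    threshold_n: float | None = None,
) -> tuple[ForceTrace, LandingMetrics]:
    """Average repeated trials of one condition, preserving each trial's impulse.

    Each trial's landing phase is linearly rescaled in time to the mean
    landing duration, then rescaled in amplitude by the ratio of its original
    to its rescaled impulse, so the transformed trial carries exactly the
    impulse of the original.  The averaged profile is the point-wise mean on
    the common grid; its impulse therefore equals the arithmetic mean of the
    trial impulses.

    Returns the averaged profile (as a trace with the force split evenly
    between plates) and its extracted metrics.
    """
    if len(traces) < 2:
        raise ValidationError("averaging requires at least 2 trials")
    if threshold_n is None:
        threshold_n = bw_n
    fs = traces[0].fs_hz
    for i, tr in enumerate(traces[1:], start=2):
        if abs(tr.fs_hz - fs) > 1e-6:
            raise ValidationError(
                f"heterogeneous sampling rates: trial 1 at {fs} Hz, trial {i} "
                f"at {tr.fs_hz} Hz"
            )
    phases = []
    impulses = []
    for i, tr in enumerate(traces, start=1):
        try:
            lo, hi = landing_phase(tr, threshold_n)
        except NoContactError as err:
            raise ValidationError(f"trial {i} has no landing phase: {err}") from err
        f = total_force(tr)[lo : hi + 1]
        t = tr.time_s[lo : hi + 1]
        phases.append((t - t[0], f))
        impulses.append(impulse(f, time_s=t))

    t_av = float(np.mean([t[-1] for t, _ in phases]))
    n_out = int(round(t_av * fs)) + 1
    grid = np.arange(n_out) / fs

    rescaled = []
    for (t, f), imp_orig in zip(phases, impulses):
        f_new = _resample_phase(t, f, n_out)
        imp_new = impulse(f_new, time_s=grid)
        rescaled.append(f_new * (imp_orig / imp_new))
    avg = np.mean(rescaled, axis=0)

    avg_trace = ForceTrace(time_s=grid, fz_left_n=avg / 2, fz_right_n=avg / 2)
    warns: list[str] = []
    peak = peak_grf_bw(avg, bw_n)
    t_abs = absorption_time(avg, threshold_n, 0, time_s=grid, warn_sink=warns)
    metrics = LandingMetrics(
        peak_grf_bw=peak,
        t_abs_s=t_abs,
        impulse_ns=float(np.mean(impulses)),
        contact_index=0,
        bw_n=bw_n,
        warnings=warns,
    )
    return avg_trace, metrics
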