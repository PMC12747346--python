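"""Synthetic vertical ground-reaction-force waveforms for drop landings.

A landing trace is modelled piecewise: a flight (zero-force) segment, a
monotone rise to the supported weight, a raised-sine impact bump whose
supra-weight duration and peak multiple are exact by construction, and a
quiet-stance plateau at the supported weight.  The analytic form makes
parameter-recovery tests exact: the noise-free trace crosses the weight
level precisely at the bump boundaries and attains its maximum at the bump
midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grf import ForceTrace

__all__ = ["WaveformParams", "make_waveform"]


class ValidationError(ValueError):
    """Raised when a parameter violates its documented constraint."""


@dataclass(frozen=True)
class WaveformParams:
    """Parameters of one synthetic landing trace.

    Attributes
    ----------
    bw_n:
        Supported weight in newtons; the plateau level and the reference for
        the bump anatomy.  When protective gear is worn this is body plus
        gear weight.
    peak_bw:
        Target peak force as a multiple of ``bw_n`` (must exceed 1).
    t_abs_s:
        Target duration of the supra-weight bump, seconds.
    t_rise_s:
        Rise time from zero force to ``bw_n`` before the bump, seconds.
    shape_q:
        Positive exponent applied to the raised-sine bump; 1 gives a plain
        half-sine, larger values sharpen the peak.
    fs_hz:
        Sampling rate, Hz (>= 200).
    pre_contact_s:
        Flight padding of zero force before ground contact, seconds.
    settle_s:
        Quiet-stance plateau after the bump, seconds.
    noise_sd_bw:
        SD of additive white noise in units of ``bw_n``.
    left_share:
        Fraction of the total force assigned to the left plate, in [0, 1].
    """

    bw_n: float
    peak_bw: float
    t_abs_s: float
    t_rise_s: float = 0.05
    shape_q: float = 1.0
    fs_hz: float = 1000.0
    pre_contact_s: float = 0.2
    settle_s: float = 0.5
    noise_sd_bw: float = 0.0
    left_share: float = 0.5

    def __post_init__(self) -> None:
        checks = [
            ("bw_n", self.bw_n > 0),
            ("peak_bw", self.peak_bw > 1),
            ("t_abs_s", self.t_abs_s > 0),
            ("t_rise_s", self.t_rise_s > 0),
            ("shape_q", self.shape_q > 0),
            ("fs_hz", self.fs_hz >= 200),
            ("pre_contact_s", self.pre_contact_s >= 0),
            ("settle_s", self.settle_s >= 0),
            ("noise_sd_bw", self.noise_sd_bw >= 0),
            ("left_share", 0 <= self.left_share <= 1),
        ]
        for name, ok in checks:
            if not ok:
                raise ValidationError(
                    f"invalid waveform parameter {name}={getattr(self, name)!r}"
                )


def make_waveform(params: WaveformParams, rng: np.random.Generator) -> ForceTrace:
    """Synthesise one landing trial as a two-plate force trace.

    The noise-free construction is piecewise:

    * zero force for ``pre_contact_s``;
    * linear rise from 0 to ``bw_n`` over ``t_rise_s``;
    * for t in [t1, t1 + t_abs_s] (t1 = contact + rise):
      ``F = bw_n + (peak_bw - 1) * bw_n * sin(pi * (t - t1) / t_abs_s) ** shape_q``;
    * constant ``bw_n`` for ``settle_s``.

    Gaussian noise of SD ``noise_sd_bw * bw_n`` is added per sample after
    construction, and the total is then split across the two plates by
    ``left_share`` so the plate sum reconstructs the total exactly.
    """
    p = params
    dt = 1.0 / p.fs_hz
    duration = p.pre_contact_s + p.t_rise_s + p.t_abs_s + p.settle_s
    n = int(round(duration * p.fs_hz)) + 1
    t = np.arange(n) * dt

    t_contact = p.pre_contact_s
    t1 = t_contact + p.t_rise_s
    t2 = t1 + p.t_abs_s

    force = np.zeros(n)
    rise = (t >= t_contact) & (t < t1)
    force[rise] = p.bw_n * (t[rise] - t_contact) / p.t_rise_s
    bump = (t >= t1) & (t <= t2)
    phase = np.pi * (t[bump] - t1) / p.t_abs_s
    force[bump] = p.bw_n + (p.peak_bw - 1.0) * p.bw_n * np.sin(phase) ** p.shape_q
    force[t > t2] = p.bw_n

    if p.noise_sd_bw > 0:
        force = force + rng.normal(0.0, p.noise_sd_bw * p.bw_n, size=n)

    # right plate is the exact complement so the plate sum reconstructs the
    # total bit-exactly (a plateau equal to the weight must not drift above it)
    left = force * p.left_share
    return ForceTrace(time_s=t, fz_left_n=left, fz_right_n=force - left)
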