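"""Synthetic cohort generator for the drop-landing study design.

Emulates a cohort of firefighters in three age groups performing drop
landings under a full factorial of two clothing conditions (sportswear "S"
and fire-protection gear "FP", the latter adding ~75 N) and two platform
heights (0.5 m and 1.0 m), with three trials per condition.  Per-subject
overload levels (peak GRF/BW and impact-absorption time) are drawn from a
Gaussian copula over lognormal marginals, giving strictly positive values
with a controllable between-subject correlation, and are rendered into
force-plate traces by :mod:`dropload.waveform`.  Every generated parameter
is recorded in a truth table so downstream extraction can be validated
against ground truth.

The default calibration (group sizes, anthropometry, strength indices, and
condition means) reproduces the published summary statistics of the cohort
this generator emulates; the peak-GRF cells not published are documented
defaults consistent with the published height effects and group ordering.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .waveform import WaveformParams, make_waveform, ValidationError
from .grf import ForceTrace

__all__ = [
    "AGE_GROUPS",
    "CLOTHING",
    "HEIGHTS_M",
    "CohortDesign",
    "SubjectProfile",
    "Trial",
    "Cohort",
    "make_cohort",
    "torques_from_summary",
    "default_condition_means",
    "CorrelationError",
    "GRAVITY_MS2",
]

GRAVITY_MS2 = 9.81

AGE_GROUPS = ("I", "II", "III")
CLOTHING = ("S", "FP")
HEIGHTS_M = (0.5, 1.0)

#: published cohort sizes per age group
DEFAULT_GROUP_SIZES: dict[str, int] = {"I": 83, "II": 38, "III": 50}

#: body mass mean/SD (kg) and body height mean/SD (cm) per age group
ANTHROPOMETRY: dict[str, dict[str, float]] = {
    "I": {"mass_mean": 79.5, "mass_sd": 8.36, "height_mean": 180.6, "height_sd": 6.80},
    "II": {"mass_mean": 89.7, "mass_sd": 9.39, "height_mean": 179.9, "height_sd": 4.79},
    "III": {"mass_mean": 87.2, "mass_sd": 13.25, "height_mean": 178.0, "height_sd": 5.03},
}

#: summed knee torque ST (N·m) and H/Q index (%) mean/SD per age group
STRENGTH_CALIBRATION: dict[str, dict[str, float]] = {
    "I": {"st_mean": 385.2, "st_sd": 62.2, "hq_mean": 42.8, "hq_sd": 10.0},
    "II": {"st_mean": 371.1, "st_sd": 63.1, "hq_mean": 40.3, "hq_sd": 13.8},
    "III": {"st_mean": 336.4, "st_sd": 57.7, "hq_mean": 41.8, "hq_sd": 10.9},
}

#: impact-absorption time condition means, seconds, keyed (group, clothing, height)
T_ABS_MEANS_S: dict[tuple[str, str, float], float] = {
    ("I", "S", 0.5): 0.29, ("I", "FP", 0.5): 0.36,
    ("II", "S", 0.5): 0.36, ("II", "FP", 0.5): 0.38,
    ("III", "S", 0.5): 0.38, ("III", "FP", 0.5): 0.40,
    ("I", "S", 1.0): 0.41, ("I", "FP", 1.0): 0.48,
    ("II", "S", 1.0): 0.46, ("II", "FP", 1.0): 0.47,
    ("III", "S", 1.0): 0.47, ("III", "FP", 1.0): 0.50,
}

#: peak GRF/BW condition means (body-weight multiples).  Only the group-I
#: sport/0.5 m (5.6) and group-I FP/1.0 m (8.9) cells are published; the
#: remaining cells are package defaults consistent with the published
#: per-group height effects (+39/+33/+40 % from 0.5 to 1.0 m), the FP/S
#: ratio implied by the two published cells (~1.14), and the published
#: group ordering I > II > III.
PEAK_BW_MEANS: dict[tuple[str, str, float], float] = {
    ("I", "S", 0.5): 5.6, ("I", "FP", 0.5): 6.4,
    ("I", "S", 1.0): 7.8, ("I", "FP", 1.0): 8.9,
    ("II", "S", 0.5): 5.0, ("II", "FP", 0.5): 5.7,
    ("II", "S", 1.0): 6.7, ("II", "FP", 1.0): 7.6,
    ("III", "S", 0.5): 4.7, ("III", "FP", 0.5): 5.4,
    ("III", "S", 1.0): 6.6, ("III", "FP", 1.0): 7.5,
}

#: default target between-subject correlation of (peak GRF/BW, t_abs) per
#: group: essentially zero in the youngest group (no overload/absorption
#: trade-off), negative in the older groups where softer landings reduce load
DEFAULT_WITHIN_CORR: dict[str, float] = {"I": 0.02, "II": -0.35, "III": -0.45}


class CorrelationError(ValueError):
    """Requested (peak, t_abs) correlation is unreachable with the marginals."""


def default_condition_means() -> dict[tuple[str, str, float], tuple[float, float]]:
    """Default (peak_bw, t_abs_s) mean per (group, clothing, height) cell."""
    return {
        key: (PEAK_BW_MEANS[key], T_ABS_MEANS_S[key])
        for key in PEAK_BW_MEANS
    }


@dataclass(frozen=True)
class CohortDesign:
    """Full factorial design plus effect/noise parameters of the generator.

    ``condition_means`` maps (age_group, clothing, height_m) to the target
    mean (peak_bw, t_abs_s) of that cell; ``subject_sd`` is the SD of a
    multiplicative subject-level random effect shared by both metrics and
    all conditions; ``cell_cv_peak``/``cell_cv_tabs`` are the between-subject
    coefficients of variation within a cell; ``trial_cv`` is the
    within-subject trial-to-trial CV; ``within_corr`` is the target
    between-subject correlation of (peak, t_abs) within a cell, either a
    scalar or a per-group mapping.
    """

    seed: int
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    condition_means: Mapping[tuple[str, str, float], tuple[float, float]] = field(
        default_factory=default_condition_means
    )
    subject_sd: float = 0.10
    cell_cv_peak: float = 0.25
    cell_cv_tabs: float = 0.25
    trial_cv: float = 0.03
    within_corr: float | Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WITHIN_CORR)
    )
    gear_load_n: float = 75.0
    trials_per_condition: int = 3
    fs_hz: float = 1000.0
    noise_sd_bw: float = 0.05
    t_rise_s: float = 0.05
    shape_q: float = 1.0
    pre_contact_s: float = 0.2
    settle_s: float = 0.5

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in AGE_GROUPS:
                raise ValidationError(f"unknown age group {g!r}")
            if n < 1:
                raise ValidationError(f"group_sizes[{g!r}] must be >= 1, got {n}")
        for g in self.group_sizes:
            for c in CLOTHING:
                for h in HEIGHTS_M:
                    if (g, c, h) not in self.condition_means:
                        raise ValidationError(
                            f"condition_means missing cell {(g, c, h)!r}"
                        )
        for g in self.group_sizes:
            r = self.corr_for(g)
            if not -1 < r < 1:
                raise ValidationError(f"within_corr must be in (-1, 1), got {r}")
        if self.gear_load_n < 0:
            raise ValidationError("gear_load_n must be >= 0")
        if self.trials_per_condition < 1:
            raise ValidationError("trials_per_condition must be >= 1")
        for name in ("subject_sd", "cell_cv_peak", "cell_cv_tabs", "trial_cv"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    def corr_for(self, group: str) -> float:
        if isinstance(self.within_corr, Mapping):
            return float(self.within_corr[group])
        return float(self.within_corr)


@dataclass(frozen=True)
class SubjectProfile:
    """One subject's anthropometrics, group label and isometric torques."""

    subject_id: str
    age_group: str
    mass_kg: float
    height_cm: float
    t_ext_nm: float
    t_flex_nm: float

    def __post_init__(self) -> None:
        for name in ("mass_kg", "height_cm", "t_ext_nm", "t_flex_nm"):
            if getattr(self, name) <= 0:
                raise ValidationError(
                    f"{name} must be positive, got {getattr(self, name)}"
                )
        if self.age_group not in AGE_GROUPS:
            raise ValidationError(f"unknown age group {self.age_group!r}")

    @classmethod
    def from_record(cls, record: Mapping) -> "SubjectProfile":
        return cls(**{f.name: record[f.name] for f in dataclasses.fields(cls)})


@dataclass(frozen=True)
class Trial:
    """One generated landing trial with its design coordinates."""

    subject_id: str
    age_group: str
    clothing: str
    height_m: float
    trial: int
    trace: ForceTrace


@dataclass(frozen=True)
class Cohort:
    """Generator output: subject table, trials, and ground-truth table."""

    subjects: pd.DataFrame
    trials: list[Trial]
    truth: pd.DataFrame
    design: CohortDesign


def torques_from_summary(st_nm: float, hq_pct: float) -> tuple[float, float]:
    """Invert (ST, H/Q) into (extensor, flexor) torques.

    Solves ``st = t_ext + t_flex`` and ``hq = (1 - t_flex/t_ext) * 100``:
    ``t_ext = st / (2 - hq/100)``, ``t_flex = st - t_ext``.  Round-trips
    exactly through :func:`dropload.strength.hq_ratio` and
    :func:`dropload.strength.summed_torque`.
    """
    if st_nm <= 0:
        raise ValidationError(f"summed torque must be positive, got {st_nm}")
    if hq_pct >= 100:
        raise ValidationError(
            f"H/Q index must be < 100 (flexor torque would be <= 0), got {hq_pct}"
        )
    t_ext = st_nm / (2.0 - hq_pct / 100.0)
    t_flex = st_nm - t_ext
    return t_ext, t_flex


def _lognorm_sigma(cv: float) -> float:
    """Log-scale SD of a lognormal with coefficient of variation ``cv``."""
    return math.sqrt(math.log1p(cv * cv))


def _copula_rho(
    target_corr: float, s_subj: float, s_peak: float, s_tabs: float
) -> float:
    """Log-scale correlation of the cell-level draw achieving ``target_corr``.

    The generated pair is (m_p·u·e_p, m_t·u·e_t) with u, e_p, e_t jointly
    lognormal: log-variances s_subj² (shared) and s_peak²/s_tabs² with
    log-correlation rho between e_p and e_t.  The Pearson correlation of a
    bivariate lognormal pair with log-covariance c and log-variances v1, v2
    is (exp(c) - 1) / sqrt((exp(v1) - 1)(exp(v2) - 1)); inverting for rho
    yields the required copula parameter.  Raises CorrelationError when no
    rho in [-1, 1] attains the target.
    """
    if s_peak == 0 or s_tabs == 0:
        if target_corr != 0:
            raise CorrelationError(
                f"correlation {target_corr} unreachable: a marginal has zero "
                "between-subject variance"
            )
        return 0.0
    v1 = s_subj**2 + s_peak**2
    v2 = s_subj**2 + s_tabs**2
    denom = math.sqrt(math.expm1(v1) * math.expm1(v2))
    inner = 1.0 + target_corr * denom
    if inner <= 0:
        raise CorrelationError(
            f"correlation {target_corr} unreachable with lognormal marginals "
            f"(CVs {math.sqrt(math.expm1(v1)):.3f}, {math.sqrt(math.expm1(v2)):.3f})"
        )
    rho = (math.log(inner) - s_subj**2) / (s_peak * s_tabs)
    if not -1.0 <= rho <= 1.0:
        raise CorrelationError(
            f"correlation {target_corr} requires copula correlation {rho:.3f} "
            "outside [-1, 1]; reduce |within_corr| or the shared subject effect"
        )
    return rho


def _lognormal_pair(
    rng: np.random.Generator, sig1: float, sig2: float, rho: float
) -> tuple[float, float]:
    """Unit-mean correlated lognormal pair with log-SDs sig1, sig2."""
    z = rng.multivariate_normal(
        [0.0, 0.0], [[1.0, rho], [rho, 1.0]], method="cholesky"
    )
    a = math.exp(sig1 * z[0] - 0.5 * sig1 * sig1)
    b = math.exp(sig2 * z[1] - 0.5 * sig2 * sig2)
    return a, b


def _unit_lognormal(rng: np.random.Generator, sigma: float) -> float:
    if sigma == 0:
        return 1.0
    return float(rng.lognormal(-0.5 * sigma * sigma, sigma))


def make_cohort(design: CohortDesign, with_traces: bool = True) -> Cohort:
    """Generate a full synthetic cohort.

    Deterministic given ``design`` (including its seed): each subject draws
    from an independent stream derived from ``(seed, subject counter)``, so
    the output is invariant to generation order.  In the fire-protection
    condition the waveform is shaped by the supported weight (body + gear)
    while body-only weight is recorded for normalisation, so the true peak
    GRF/BW stored in the truth table is on the body-only convention.

    With ``with_traces=False`` only the subject and truth tables are built,
    which is much faster when force traces are not needed.
    """
    s_subj = _lognorm_sigma(design.subject_sd)
    s_peak = _lognorm_sigma(design.cell_cv_peak)
    s_tabs = _lognorm_sigma(design.cell_cv_tabs)
    s_trial = _lognorm_sigma(design.trial_cv)
    rho_by_group = {
        g: _copula_rho(design.corr_for(g), s_subj, s_peak, s_tabs)
        for g in design.group_sizes
    }

    subject_rows = []
    truth_rows = []
    trials: list[Trial] = []
    counter = 0
    for group in AGE_GROUPS:
        n_g = design.group_sizes.get(group, 0)
        anth = ANTHROPOMETRY[group]
        cal = STRENGTH_CALIBRATION[group]
        rho = rho_by_group.get(group, 0.0)
        for i_subj in range(n_g):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(design.seed), counter])
            )
            counter += 1
            sid = f"{group}{i_subj + 1:03d}"
            mass = max(45.0, rng.normal(anth["mass_mean"], anth["mass_sd"]))
            height = rng.normal(anth["height_mean"], anth["height_sd"])
            st = max(60.0, rng.normal(cal["st_mean"], cal["st_sd"]))
            hq = min(95.0, rng.normal(cal["hq_mean"], cal["hq_sd"]))
            t_ext, t_flex = torques_from_summary(st, hq)
            subject_rows.append(
                dict(
                    subject_id=sid,
                    age_group=group,
                    mass_kg=mass,
                    height_cm=height,
                    t_ext_nm=t_ext,
                    t_flex_nm=t_flex,
                )
            )
            bw_body = mass * GRAVITY_MS2
            u = _unit_lognormal(rng, s_subj)
            for clothing in CLOTHING:
                bw_eff = bw_body + (
                    design.gear_load_n if clothing == "FP" else 0.0
                )
                for height_m in HEIGHTS_M:
                    m_peak, m_tabs = design.condition_means[(group, clothing, height_m)]
                    e_peak, e_tabs = _lognormal_pair(rng, s_peak, s_tabs, rho)
                    subj_peak = m_peak * u * e_peak
                    subj_tabs = m_tabs * u * e_tabs
                    for i_trial in range(1, design.trials_per_condition + 1):
                        true_peak = subj_peak * _unit_lognormal(rng, s_trial)
                        true_tabs = subj_tabs * _unit_lognormal(rng, s_trial)
                        # peak is a body-only BW multiple; the waveform bump
                        # anatomy is referenced to the supported weight
                        peak_eff = true_peak * bw_body / bw_eff
                        if peak_eff <= 1.0:
                            peak_eff = 1.0 + 1e-6
                            true_peak = peak_eff * bw_eff / bw_body
                        left_share = float(np.clip(rng.normal(0.5, 0.02), 0.3, 0.7))
                        truth_rows.append(
                            dict(
                                subject_id=sid,
                                age_group=group,
                                clothing=clothing,
                                height_m=height_m,
                                trial=i_trial,
                                mass_kg=mass,
                                bw_n=bw_body,
                                bw_eff_n=bw_eff,
                                true_peak_grf_bw=true_peak,
                                true_t_abs_s=true_tabs,
                                subject_effect=u,
                                left_share=left_share,
                            )
                        )
                        if with_traces:
                            params = WaveformParams(
                                bw_n=bw_eff,
                                peak_bw=peak_eff,
                                t_abs_s=true_tabs,
                                t_rise_s=design.t_rise_s,
                                shape_q=design.shape_q,
                                fs_hz=design.fs_hz,
                                pre_contact_s=design.pre_contact_s,
                                settle_s=design.settle_s,
                                noise_sd_bw=design.noise_sd_bw,
                                left_share=left_share,
                            )
                            trials.append(
                                Trial(
                                    subject_id=sid,
                                    age_group=group,
                                    clothing=clothing,
                                    height_m=height_m,
                                    trial=i_trial,
                                    trace=make_waveform(params, rng),
                                )
                            )

    subjects = pd.DataFrame(subject_rows)
    truth = pd.DataFrame(truth_rows)
    return Cohort(subjects=subjects, trials=trials, truth=truth, design=design)
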