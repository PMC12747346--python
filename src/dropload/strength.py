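"""Knee-joint strength indices from isometric torques.

Two scalars summarise each subject's knee strength profile: the summed
torque ST = T_ext + T_flex (N·m) and the H/Q stability index
``(1 - T_flex / T_ext) * 100`` (%).  Values of the index above 50 indicate
an at-least-twofold extensor advantage; negative values mean the flexors
out-torque the extensors.  Note this index is *not* the conventional
hamstring:quadriceps quotient ``T_flex / T_ext * 100``, which is provided
separately as :func:`conventional_hq_ratio`.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "StrengthRecord",
    "strength_record",
    "hq_ratio",
    "conventional_hq_ratio",
    "summed_torque",
    "append_strength_columns",
]


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class StrengthRecord:
    t_ext_nm: float
    t_flex_nm: float
    st_nm: float
    hq_pct: float


def hq_ratio(t_flex_nm: float, t_ext_nm: float) -> float:
    """H/Q stability index, percent: ``(1 - T_flex/T_ext) * 100``.

    Strictly decreasing in flexor torque and increasing in extensor torque;
    may be negative when flexors exceed extensors (no clamping).
    """
    if t_ext_nm <= 0:
        raise ValidationError(f"extensor torque must be positive, got {t_ext_nm}")
    return (1.0 - t_flex_nm / t_ext_nm) * 100.0


def conventional_hq_ratio(t_flex_nm: float, t_ext_nm: float) -> float:
    """Conventional hamstring:quadriceps quotient, percent: T_flex/T_ext × 100."""
    if t_ext_nm <= 0:
        raise ValidationError(f"extensor torque must be positive, got {t_ext_nm}")
    return t_flex_nm / t_ext_nm * 100.0


def summed_torque(t_flex_nm: float, t_ext_nm: float) -> float:
    """Summed knee torque ST = T_flex + T_ext, N·m."""
    if t_flex_nm < 0 or t_ext_nm < 0:
        raise ValidationError(
            f"torques must be non-negative, got flex={t_flex_nm}, ext={t_ext_nm}"
        )
    return t_flex_nm + t_ext_nm


def strength_record(t_flex_nm: float, t_ext_nm: float) -> StrengthRecord:
    return StrengthRecord(
        t_ext_nm=t_ext_nm,
        t_flex_nm=t_flex_nm,
        st_nm=summed_torque(t_flex_nm, t_ext_nm),
        hq_pct=hq_ratio(t_flex_nm, t_ext_nm),
    )


def append_strength_columns(subjects: pd.DataFrame) -> pd.DataFrame:
    """Append ``st_nm`` and ``hq_pct`` columns to a subject table.

    Expects ``t_ext_nm`` and ``t_flex_nm`` columns; returns a copy.
    """
    out = subjects.copy()
    if (out["t_ext_nm"] <= 0).any():
        bad = out.loc[out["t_ext_nm"] <= 0, "subject_id"].tolist()
        raise ValidationError(f"non-positive extensor torque for subjects {bad}")
    out["st_nm"] = out["t_ext_nm"] + out["t_flex_nm"]
    out["hq_pct"] = (1.0 - out["t_flex_nm"] / out["t_ext_nm"]) * 100.0
    return out
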