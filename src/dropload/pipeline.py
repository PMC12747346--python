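"""End-to-end run orchestration: generate → extract → summarize → test → report.

A run is driven by a :class:`RunConfig`.  In ``simulate`` mode a synthetic
cohort is generated from a :class:`~dropload.cohort.CohortDesign`; in
``analyze`` mode trial files and a subject table are read from disk.  Both
modes then share the same downstream stages: per-trial metric extraction,
impulse-preserving trial averaging per condition, condition mean±SD tables,
the mixed repeated-measures ANOVA battery, Tukey post-hoc tables, the
per-group correlation table between overload and absorption time, and
linear regressions of overload on absorption time and on the H/Q index.
A manifest records the configuration hash, seed and library versions, so a
repeated run with the same config and seed produces an identical bundle.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as dio
from .cohort import (
    CohortDesign,
    GRAVITY_MS2,
    Trial,
    default_condition_means,
    make_cohort,
)
from .grf import average_trials, extract_metrics
from .rmstats import (
    UndefinedCorrelationError,
    linfit,
    mixed_rm_anova,
    one_way_anova,
    pearson_corr,
    tukey_posthoc,
)
from .strength import append_strength_columns

__all__ = ["RunConfig", "run", "ConfigError", "cohort_metrics", "design_from_dict"]

log = logging.getLogger("dropload")

BW_CONVENTIONS = ("body_only", "body_plus_gear")
AVERAGING_MODES = ("profile_first", "metrics_first")


class ConfigError(ValueError):
    """A run configuration field is missing or invalid."""


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one pipeline run."""

    mode: str
    seed: int
    out_dir: Path
    design: CohortDesign | None = None
    trials_dir: Path | None = None
    subject_table: Path | None = None
    bw_convention: str = "body_only"
    averaging: str = "profile_first"
    write_trials: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "analyze"):
            raise ConfigError(f"mode must be simulate or analyze, got {self.mode!r}")
        if self.bw_convention not in BW_CONVENTIONS:
            raise ConfigError(
                f"bw_convention must be one of {BW_CONVENTIONS}, "
                f"got {self.bw_convention!r}"
            )
        if self.averaging not in AVERAGING_MODES:
            raise ConfigError(
                f"averaging must be one of {AVERAGING_MODES}, got {self.averaging!r}"
            )
        if self.mode == "simulate" and self.design is None:
            raise ConfigError("simulate mode requires a design section")
        if self.mode == "analyze":
            if self.trials_dir is None or self.subject_table is None:
                raise ConfigError(
                    "analyze mode requires trials_dir and subject_table paths"
                )


def design_from_dict(d: dict, seed: int) -> CohortDesign:
    """Build a CohortDesign from a config mapping (YAML-friendly form).

    ``condition_means`` entries, when given, are keyed "GROUP,CLOTHING,HEIGHT"
    (e.g. ``"I,S,0.5"``) with value ``[peak_bw, t_abs_s]``; omitted cells keep
    the packaged defaults.
    """
    d = dict(d)
    means = default_condition_means()
    for key, val in (d.pop("condition_means", None) or {}).items():
        try:
            g, c, h = [part.strip() for part in str(key).split(",")]
            cell = (g, c, float(h))
            peak, tabs = float(val[0]), float(val[1])
        except (ValueError, IndexError, TypeError) as err:
            raise ConfigError(
                f"malformed condition_means entry {key!r}: {err}"
            ) from err
        if cell not in means:
            raise ConfigError(f"unknown condition_means cell {key!r}")
        means[cell] = (peak, tabs)
    known = {f.name for f in dataclasses.fields(CohortDesign)}
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown design fields: {sorted(unknown)}")
    if "group_sizes" in d:
        d["group_sizes"] = {str(k): int(v) for k, v in d["group_sizes"].items()}
    d.pop("seed", None)
    try:
        return CohortDesign(seed=seed, condition_means=means, **d)
    except ValueError as err:
        raise ConfigError(str(err)) from err


def config_from_file(path: str | Path, seed_override: int | None = None) -> RunConfig:
    raw = dio.load_config(path)
    mode = raw.get("mode")
    if mode is None:
        raise ConfigError("config field 'mode' is required")
    seed = seed_override if seed_override is not None else raw.get("seed")
    if seed is None:
        raise ConfigError("config field 'seed' is required")
    design = None
    if mode == "simulate":
        design = design_from_dict(raw.get("design") or {}, seed=int(seed))
    paths = raw.get("paths") or {}
    return RunConfig(
        mode=str(mode),
        seed=int(seed),
        out_dir=Path(raw.get("out_dir", "dropload_out")),
        design=design,
        trials_dir=Path(paths["trials_dir"]) if "trials_dir" in paths else None,
        subject_table=(
            Path(paths["subject_table"]) if "subject_table" in paths else None
        ),
        bw_convention=raw.get("bw_convention", "body_only"),
        averaging=raw.get("averaging", "profile_first"),
        write_trials=bool(raw.get("write_trials", True)),
        log_level=str(raw.get("log_level", "INFO")),
    )


def cohort_metrics(
    trials: list[Trial],
    subjects: pd.DataFrame,
    gear_load_n: float = 75.0,
    bw_convention: str = "body_only",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract per-trial and per-condition metrics for a whole cohort.

    Returns ``(trial_metrics, condition_metrics)``.  ``trial_metrics`` has
    one row per trial; ``condition_metrics`` one row per subject × clothing
    × height with both averaging conventions: metrics of the averaged
    profile (``*_profile``) and the mean of per-trial metrics (``*_mean``).

    The supra-weight threshold that delimits the absorption interval always
    uses the supported weight (body plus gear in the FP condition); the
    ``bw_convention`` flag only selects the weight used to normalise the
    peak force.
    """
    bw_body = subjects.set_index("subject_id")["mass_kg"] * GRAVITY_MS2
    group_of = subjects.set_index("subject_id")["age_group"]

    trial_rows = []
    cond_rows = []
    keyfunc = lambda tr: (tr.subject_id, tr.clothing, tr.height_m)
    n_zero_tabs = 0
    for (sid, clothing, height), grp in itertools.groupby(
        sorted(trials, key=lambda tr: (tr.subject_id, tr.clothing, tr.height_m, tr.trial)),
        key=keyfunc,
    ):
        grp = list(grp)
        if sid not in bw_body.index:
            raise dio.InputFileError(
                f"trial subject {sid!r} missing from the subject table"
            )
        body = float(bw_body[sid])
        supported = body + (gear_load_n if clothing == "FP" else 0.0)
        norm = supported if (
            bw_convention == "body_plus_gear" and clothing == "FP"
        ) else body
        per_trial = []
        for tr in grp:
            m = extract_metrics(tr.trace, norm, threshold_n=supported)
            if m.t_abs_s == 0.0:
                n_zero_tabs += 1
                log.warning(
                    "zero absorption time: subject %s %s %.1f m trial %d",
                    sid, clothing, height, tr.trial,
                )
            per_trial.append(m)
            trial_rows.append(
                dict(
                    subject_id=sid,
                    age_group=group_of[sid],
                    clothing=clothing,
                    height_m=height,
                    trial=tr.trial,
                    peak_grf_bw=m.peak_grf_bw,
                    t_abs_s=m.t_abs_s,
                    impulse_ns=m.impulse_ns,
                    contact_index=m.contact_index,
                    bw_n=m.bw_n,
                )
            )
        row = dict(
            subject_id=sid,
            age_group=group_of[sid],
            clothing=clothing,
            height_m=height,
            n_trials=len(grp),
            peak_grf_bw_mean=float(np.mean([m.peak_grf_bw for m in per_trial])),
            t_abs_s_mean=float(np.mean([m.t_abs_s for m in per_trial])),
            impulse_ns_mean=float(np.mean([m.impulse_ns for m in per_trial])),
        )
        if len(grp) >= 2:
            _, avg_m = average_trials(
                [tr.trace for tr in grp], norm, threshold_n=supported
            )
            row.update(
                peak_grf_bw_profile=avg_m.peak_grf_bw,
                t_abs_s_profile=avg_m.t_abs_s,
                impulse_ns_profile=avg_m.impulse_ns,
            )
        else:
            row.update(
                peak_grf_bw_profile=row["peak_grf_bw_mean"],
                t_abs_s_profile=row["t_abs_s_mean"],
                impulse_ns_profile=row["impulse_ns_mean"],
            )
        cond_rows.append(row)
    if n_zero_tabs:
        log.warning("%d trial(s) never exceeded the weight threshold", n_zero_tabs)
    return pd.DataFrame(trial_rows), pd.DataFrame(cond_rows)


def _long_table(cond: pd.DataFrame, metric: str, averaging: str) -> pd.DataFrame:
    suffix = "profile" if averaging == "profile_first" else "mean"
    out = cond[
        ["subject_id", "age_group", "clothing", "height_m", f"{metric}_{suffix}"]
    ].rename(columns={f"{metric}_{suffix}": "value"})
    return out


def _condition_summary(cond: pd.DataFrame, averaging: str) -> pd.DataFrame:
    suffix = "profile" if averaging == "profile_first" else "mean"
    rows = []
    for (g, c, h), grp in cond.groupby(["age_group", "clothing", "height_m"]):
        rows.append(
            dict(
                age_group=g,
                clothing=c,
                height_m=h,
                n=len(grp),
                peak_grf_bw_mean=grp[f"peak_grf_bw_{suffix}"].mean(),
                peak_grf_bw_sd=grp[f"peak_grf_bw_{suffix}"].std(ddof=1),
                t_abs_s_mean=grp[f"t_abs_s_{suffix}"].mean(),
                t_abs_s_sd=grp[f"t_abs_s_{suffix}"].std(ddof=1),
            )
        )
    return pd.DataFrame(rows)


def _anova_frame(results) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in results])


def _correlation_table(cond: pd.DataFrame, averaging: str) -> pd.DataFrame:
    """Pearson r and p between peak GRF/BW and t_abs per group × condition."""
    suffix = "profile" if averaging == "profile_first" else "mean"
    rows = []
    for (g, c, h), grp in cond.groupby(["age_group", "clothing", "height_m"]):
        try:
            r, p = pearson_corr(
                grp[f"t_abs_s_{suffix}"], grp[f"peak_grf_bw_{suffix}"]
            )
        except (UndefinedCorrelationError, ValueError):
            r, p = float("nan"), float("nan")
        rows.append(
            dict(age_group=g, clothing=c, height_m=h, n=len(grp), r=r, p_value=p)
        )
    return pd.DataFrame(rows)


def _regression_table(
    cond: pd.DataFrame, averaging: str, x_col: str, x_name: str
) -> pd.DataFrame:
    suffix = "profile" if averaging == "profile_first" else "mean"
    rows = []
    for (g, c, h), grp in cond.groupby(["age_group", "clothing", "height_m"]):
        try:
            a, b, r2 = linfit(grp[x_col], grp[f"peak_grf_bw_{suffix}"])
        except ValueError:
            a = b = r2 = float("nan")
        rows.append(
            dict(
                age_group=g,
                clothing=c,
                height_m=h,
                x=x_name,
                intercept_a=a,
                slope_b=b,
                r2=r2,
            )
        )
    return pd.DataFrame(rows)


def _group_summary(subjects: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean±SD of anthropometric and strength variables with the
    one-way age-group ANOVA per variable."""
    subjects = append_strength_columns(subjects)
    rows = []
    for var in ("mass_kg", "height_cm", "st_nm", "hq_pct"):
        res = one_way_anova(subjects[var], subjects["age_group"])
        row = dict(variable=var, f_stat=res.f_stat, df_num=res.df_num,
                   df_den=res.df_den, p_value=res.p_value,
                   partial_eta2=res.partial_eta2)
        for g, grp in subjects.groupby("age_group"):
            row[f"mean_{g}"] = grp[var].mean()
            row[f"sd_{g}"] = grp[var].std(ddof=1)
        rows.append(row)
    return pd.DataFrame(rows)


def report(bundle_dir: str | Path, averaging: str = "profile_first") -> dict[str, Path]:
    """Rebuild the summary and statistics tables of an existing bundle.

    Reads ``condition_metrics.csv`` and ``subjects.csv`` from ``bundle_dir``
    and rewrites the condition summary, ANOVA, post-hoc, correlation and
    regression tables, e.g. after switching the averaging convention.
    """
    out = Path(bundle_dir)
    cond = dio.read_table(out / "condition_metrics.csv")
    subjects = dio.read_table(out / "subjects.csv")
    if averaging not in AVERAGING_MODES:
        raise ConfigError(f"averaging must be one of {AVERAGING_MODES}")
    bundle: dict[str, Path] = {}
    dio.write_table(_condition_summary(cond, averaging), out / "condition_summary.csv")
    bundle["condition_summary"] = out / "condition_summary.csv"
    multi_group = subjects["age_group"].nunique() > 1
    for metric in ("peak_grf_bw", "t_abs_s"):
        longt = _long_table(cond, metric, averaging)
        res = mixed_rm_anova(longt, between="age_group" if multi_group else None)
        dio.write_table(_anova_frame(res), out / f"anova_{metric}.csv")
        bundle[f"anova_{metric}"] = out / f"anova_{metric}.csv"
    dio.write_table(_correlation_table(cond, averaging), out / "correlations.csv")
    bundle["correlations"] = out / "correlations.csv"
    suffix = "profile" if averaging == "profile_first" else "mean"
    dio.write_table(
        _regression_table(cond, averaging, f"t_abs_s_{suffix}", "t_abs_s"),
        out / "regressions_tabs.csv",
    )
    bundle["regressions_tabs"] = out / "regressions_tabs.csv"
    return bundle


def run(config: RunConfig) -> dict[str, Path]:
    """Execute a full pipeline run; returns the paths of the written bundle."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.mode == "simulate":
        assert config.design is not None
        cohort = make_cohort(config.design)
        subjects, trials = cohort.subjects, cohort.trials
        gear = config.design.gear_load_n
        dio.write_table(cohort.truth, out / "truth.csv")
        if config.write_trials:
            dio.write_trials(trials, out / "trials")
        log.info("simulated %d subjects, %d trials", len(subjects), len(trials))
    else:
        subjects = dio.read_table(config.subject_table)
        needed = {"subject_id", "age_group", "mass_kg"}
        missing = needed - set(subjects.columns)
        if missing:
            raise dio.InputFileError(
                f"subject table {config.subject_table} lacks columns "
                f"{sorted(missing)}"
            )
        trials = dio.read_trials(config.trials_dir)
        gear = 75.0
        log.info("loaded %d subjects, %d trials", len(subjects), len(trials))

    dio.write_table(subjects, out / "subjects.csv")
    subjects_full = append_strength_columns(subjects) if (
        "t_ext_nm" in subjects.columns
    ) else subjects
    dio.write_table(subjects_full, out / "subjects_strength.csv")

    trial_metrics, cond = cohort_metrics(
        trials, subjects, gear_load_n=gear, bw_convention=config.bw_convention
    )
    dio.write_table(trial_metrics, out / "trial_metrics.csv")
    dio.write_table(cond, out / "condition_metrics.csv")
    dio.write_table(
        _condition_summary(cond, config.averaging), out / "condition_summary.csv"
    )
    log.info("extracted metrics for %d trials, %d conditions",
             len(trial_metrics), len(cond))

    bundle = {
        "subjects": out / "subjects.csv",
        "subjects_strength": out / "subjects_strength.csv",
        "trial_metrics": out / "trial_metrics.csv",
        "condition_metrics": out / "condition_metrics.csv",
        "condition_summary": out / "condition_summary.csv",
    }

    multi_group = subjects["age_group"].nunique() > 1
    enough = subjects.groupby("age_group").size().min() >= 2 and len(subjects) >= 4
    if enough:
        for metric in ("peak_grf_bw", "t_abs_s"):
            longt = _long_table(cond, metric, config.averaging)
            res = mixed_rm_anova(
                longt, between="age_group" if multi_group else None
            )
            dio.write_table(_anova_frame(res), out / f"anova_{metric}.csv")
            bundle[f"anova_{metric}"] = out / f"anova_{metric}.csv"
            posthoc = []
            for eff in (
                (["age_group"] if multi_group else []) + ["clothing", "height_m"]
            ):
                tab = tukey_posthoc(
                    longt, eff, between="age_group" if multi_group else None
                )
                tab.insert(0, "effect", eff)
                posthoc.append(tab)
            dio.write_table(pd.concat(posthoc), out / f"tukey_{metric}.csv")
            bundle[f"tukey_{metric}"] = out / f"tukey_{metric}.csv"

        dio.write_table(
            _correlation_table(cond, config.averaging), out / "correlations.csv"
        )
        bundle["correlations"] = out / "correlations.csv"
        dio.write_table(
            _regression_table(
                cond,
                config.averaging,
                "t_abs_s_" + ("profile" if config.averaging == "profile_first"
                              else "mean"),
                "t_abs_s",
            ),
            out / "regressions_tabs.csv",
        )
        bundle["regressions_tabs"] = out / "regressions_tabs.csv"
        if "hq_pct" in subjects_full.columns:
            merged = cond.merge(
                subjects_full[["subject_id", "hq_pct"]], on="subject_id"
            )
            dio.write_table(
                _regression_table(merged, config.averaging, "hq_pct", "hq_pct"),
                out / "regressions_hq.csv",
            )
            bundle["regressions_hq"] = out / "regressions_hq.csv"
        if multi_group and "hq_pct" in subjects_full.columns:
            dio.write_table(_group_summary(subjects), out / "group_summary.csv")
            bundle["group_summary"] = out / "group_summary.csv"

    cfg_dict = {
        "mode": config.mode,
        "seed": config.seed,
        "bw_convention": config.bw_convention,
        "averaging": config.averaging,
        "design": (
            {
                **{
                    f.name: getattr(config.design, f.name)
                    for f in dataclasses.fields(CohortDesign)
                    if f.name != "condition_means"
                },
                "condition_means": {
                    f"{g},{c},{h:g}": list(v)
                    for (g, c, h), v in config.design.condition_means.items()
                },
            }
            if config.design is not None
            else None
        ),
    }
    manifest = {
        "config_hash": dio.config_hash(cfg_dict),
        "seed": config.seed,
        "mode": config.mode,
        "averaging": config.averaging,
        "bw_convention": config.bw_convention,
        "n_subjects": int(len(subjects)),
        "n_trials": int(len(trials)),
        "versions": {
            "dropload": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    bundle["manifest"] = out / "manifest.json"
    return bundle
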