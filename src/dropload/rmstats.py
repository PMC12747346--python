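"""Mixed repeated-measures statistics for factorial landing designs.

The study design is one between-subject factor (age group) crossed with two
within-subject factors (clothing and drop height), each measured once per
subject and cell after trial averaging.  This module provides the classical
univariate split-plot ANOVA for that design: per-subject orthonormal
contrast scores are formed for every within effect, each effect is tested
against its own subject-level error stratum, partial eta-squared is
reported per effect, and sphericity is assessed per within effect by
Mauchly's test with the Greenhouse–Geisser epsilon applied to the degrees
of freedom when violated.  Group sizes may be unequal; within main effects
are tested on unweighted (Type III) group means, the convention of the
commercial packages used for such designs.

Post-hoc pairwise comparisons use the studentized-range (Tukey) statistic
with the error term of the matching stratum: subjects-within-groups for the
between factor, the effect-by-subject interaction for within factors.
Pearson correlation and ordinary least-squares helpers wrap scipy.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "mixed_rm_anova",
    "mauchly_test",
    "one_way_anova",
    "tukey_posthoc",
    "pearson_corr",
    "linfit",
    "IncompleteDesignError",
    "RankDeficiencyError",
    "effect_size_label",
]

DEFAULT_SUBJECT = "subject_id"
DEFAULT_BETWEEN = "age_group"
DEFAULT_WITHIN = ("clothing", "height_m")


class ValidationError(ValueError):
    pass


class IncompleteDesignError(ValueError):
    """A subject is missing one or more within-design cells."""


class RankDeficiencyError(ValueError):
    """Too few subjects (or no variance) to estimate the contrast covariance."""


class UndefinedCorrelationError(ValueError):
    """A series has zero variance; the correlation is undefined."""


@dataclass(frozen=True)
class AnovaResult:
    """One effect of the mixed repeated-measures ANOVA."""

    effect: str
    f_stat: float
    df_num: float
    df_den: float
    p_value: float
    partial_eta2: float
    ss_effect: float = float("nan")
    ss_error: float = float("nan")
    gg_epsilon: float = 1.0
    corrected: bool = False
    sphericity_w: float = 1.0
    sphericity_p: float = 1.0


def effect_size_label(partial_eta2: float) -> str:
    """Conventional size band of a partial eta-squared value."""
    if partial_eta2 < 0.01:
        return "negligible"
    if partial_eta2 < 0.06:
        return "small"
    if partial_eta2 < 0.14:
        return "medium"
    return "large"


def _orthonormal_contrasts(n_levels: int) -> np.ndarray:
    """(L, L-1) orthonormal contrast matrix orthogonal to the unit vector."""
    x = np.eye(n_levels) - 1.0 / n_levels
    q, _ = np.linalg.qr(x)
    return q[:, : n_levels - 1]


def _pivot_design(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    between: str | None,
    within: tuple[str, ...],
) -> tuple[np.ndarray, np.ndarray, list[str], list[list]]:
    """Long table -> (Y, group codes, group levels, within level lists).

    Y has one row per subject and one column per within cell, cells ordered
    by the cartesian product of the within factor levels.
    """
    levels = [sorted(data[f].unique().tolist()) for f in within]
    cells = list(itertools.product(*levels))
    m = len(cells)

    counts = data.groupby([subject, *within], sort=False).size()
    if (counts != 1).any():
        bad = sorted({idx[0] for idx in counts[counts != 1].index})
        raise IncompleteDesignError(
            f"subjects with duplicated within-cells: {bad}"
        )
    wide = data.pivot_table(
        index=subject, columns=list(within), values=dv, aggfunc="first"
    )
    wide = wide.reindex(columns=pd.MultiIndex.from_tuples(cells) if len(within) > 1
                        else [c[0] for c in cells])
    if wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)].tolist()
        raise IncompleteDesignError(f"subjects with missing within-cells: {bad}")
    if len(wide) < 2:
        raise ValidationError("need at least 2 subjects")

    if between is None:
        groups = np.zeros(len(wide), dtype=int)
        group_levels = ["all"]
    else:
        glab = data.groupby(subject)[between].agg(lambda s: s.unique())
        multi = [s for s, u in glab.items() if len(np.atleast_1d(u)) > 1]
        if multi:
            raise IncompleteDesignError(
                f"subjects assigned to multiple {between} levels: {multi}"
            )
        glab = glab.apply(lambda u: np.atleast_1d(u)[0]).reindex(wide.index)
        group_levels = sorted(pd.unique(glab).tolist())
        lut = {g: i for i, g in enumerate(group_levels)}
        groups = glab.map(lut).to_numpy()
    return wide.to_numpy(dtype=float), groups, list(map(str, group_levels)), levels


def _sphericity_from_scores(
    z: np.ndarray, groups: np.ndarray
) -> tuple[float, float, float]:
    """Mauchly W, its p-value, and Greenhouse–Geisser epsilon from contrast
    scores ``z`` (subjects x k), with the covariance pooled within groups."""
    n, k = z.shape
    if k == 1:
        return 1.0, 1.0, 1.0
    g = len(np.unique(groups))
    n_err = n - g
    if n_err < k:
        raise RankDeficiencyError(
            f"{n} subjects in {g} group(s) cannot estimate a {k}x{k} "
            "contrast covariance"
        )
    resid = z - np.vstack([z[groups == gi].mean(axis=0) for gi in np.unique(groups)])[
        np.searchsorted(np.unique(groups), groups)
    ]
    s = resid.T @ resid / n_err
    eig = np.linalg.eigvalsh(s)
    if eig[0] <= 1e-12 * max(eig[-1], 1.0):
        raise RankDeficiencyError(
            "contrast covariance is singular (zero variance in the data)"
        )
    w = float(np.prod(eig) / (eig.mean() ** k))
    d = 1.0 - (2.0 * k * k + k + 2.0) / (6.0 * k * n_err)
    chi2 = -n_err * d * math.log(w)
    df = k * (k + 1) / 2.0 - 1.0
    p = float(sps.chi2.sf(chi2, df))
    eps = float(eig.sum() ** 2 / (k * (eig**2).sum()))
    return w, p, eps


def _f_test(
    ss_eff: float, df_eff: float, ss_err: float, df_err: float, scale: float
) -> tuple[float, float, float]:
    """F statistic, p-value and partial eta-squared, degenerate-safe.

    ``scale`` sets the threshold below which a sum of squares is treated as
    exactly zero (numerical noise on constant data).
    """
    tiny = 1e-12 * max(scale, 1.0)
    if ss_eff <= tiny:
        return 0.0, 1.0, 0.0
    if ss_err <= tiny:
        return math.inf, 0.0, 1.0
    f = (ss_eff / df_eff) / (ss_err / df_err)
    p = float(sps.f.sf(f, df_eff, df_err))
    eta = ss_eff / (ss_eff + ss_err)
    return f, p, eta


def mixed_rm_anova(
    data: pd.DataFrame,
    dv: str = "value",
    subject: str = DEFAULT_SUBJECT,
    between: str | None = DEFAULT_BETWEEN,
    within: tuple[str, ...] = DEFAULT_WITHIN,
    alpha: float = 0.05,
) -> list[AnovaResult]:
    """Split-plot ANOVA: one optional between factor, crossed within factors.

    Returns one :class:`AnovaResult` per effect: the between main effect,
    every within main effect and within interaction, and their interactions
    with the between factor.  Each within effect is tested against its own
    effect-by-subject error stratum; the between effect against subjects
    within groups.  When Mauchly's test rejects sphericity for a within
    effect at ``alpha``, its degrees of freedom are multiplied by the
    Greenhouse–Geisser epsilon and the corrected p-value is reported.
    """
    y, groups, group_levels, levels = _pivot_design(
        data, dv, subject, between, within
    )
    if between is not None and len(group_levels) < 2:
        between = None  # a single group carries no between-subject effect
    return _mixed_anova_arrays(
        y, groups, levels, within, between, alpha
    )


def _group_stats(z: np.ndarray, groups: np.ndarray):
    gl = np.unique(groups)
    ns = np.array([(groups == g).sum() for g in gl], dtype=float)
    means = np.vstack([z[groups == g].mean(axis=0) for g in gl])
    resid = z - means[np.searchsorted(gl, groups)]
    return ns, means, resid


def _mixed_anova_arrays(
    y: np.ndarray,
    groups: np.ndarray,
    levels: list[list],
    within_names: tuple[str, ...],
    between: str | None,
    alpha: float = 0.05,
) -> list[AnovaResult]:
    n, m = y.shape
    scale = float(((y - y.mean()) ** 2).sum())
    k_w = len(within_names)
    contr = [_orthonormal_contrasts(len(lv)) for lv in levels]
    means_vec = [np.ones(len(lv)) / math.sqrt(len(lv)) for lv in levels]

    results: list[AnovaResult] = []

    # between stratum: subject means (orthonormal scale)
    j_full = means_vec[0]
    for v in means_vec[1:]:
        j_full = np.kron(j_full, v)
    z0 = y @ j_full
    ns, gmeans, resid0 = _group_stats(z0[:, None], groups)
    ss_subj = float((resid0**2).sum())
    df_subj = n - len(ns)
    if between is not None:
        grand_w = float((ns * gmeans[:, 0]).sum() / ns.sum())
        ss_a = float((ns * (gmeans[:, 0] - grand_w) ** 2).sum())
        f, p, eta = _f_test(ss_a, len(ns) - 1, ss_subj, df_subj, scale)
        results.append(
            AnovaResult(
                effect=between,
                f_stat=f,
                df_num=float(len(ns) - 1),
                df_den=float(df_subj),
                p_value=p,
                partial_eta2=eta,
                ss_effect=ss_a,
                ss_error=ss_subj,
            )
        )

    # within strata, one per nonempty subset of within factors
    for size in range(1, k_w + 1):
        for combo in itertools.combinations(range(k_w), size):
            c = np.ones((1, 1))
            for i in range(k_w):
                block = contr[i] if i in combo else means_vec[i][:, None]
                c = np.kron(c, block)
            z = y @ c  # (n, df_w)
            df_w = z.shape[1]
            ns, gmeans, resid = _group_stats(z, groups)
            a = len(ns)
            ss_err = float((resid**2).sum())
            df_err = (n - a) * df_w

            # sphericity of this effect's contrast set
            if df_w > 1:
                w_stat, w_p, eps = _sphericity_from_scores(z, groups)
            else:
                w_stat, w_p, eps = 1.0, 1.0, 1.0
            corrected = df_w > 1 and w_p < alpha

            name_w = " × ".join(within_names[i] for i in combo)

            # main within effect: unweighted (Type III) grand mean
            mu = gmeans.mean(axis=0)
            ss_w = float((mu**2).sum() * a * a / (1.0 / ns).sum())
            f, p, eta = _f_test(ss_w, df_w, ss_err, df_err, scale)
            if corrected and np.isfinite(f) and f > 0:
                p = float(sps.f.sf(f, df_w * eps, df_err * eps))
            results.append(
                AnovaResult(
                    effect=name_w,
                    f_stat=f,
                    df_num=float(df_w),
                    df_den=float(df_err),
                    p_value=p,
                    partial_eta2=eta,
                    ss_effect=ss_w,
                    ss_error=ss_err,
                    gg_epsilon=eps,
                    corrected=corrected,
                    sphericity_w=w_stat,
                    sphericity_p=w_p,
                )
            )

            if between is not None:
                grand_w = (ns[:, None] * gmeans).sum(axis=0) / ns.sum()
                ss_aw = float((ns[:, None] * (gmeans - grand_w) ** 2).sum())
                df_aw = (a - 1) * df_w
                f, p, eta = _f_test(ss_aw, df_aw, ss_err, df_err, scale)
                if corrected and np.isfinite(f) and f > 0:
                    p = float(sps.f.sf(f, df_aw * eps, df_err * eps))
                results.append(
                    AnovaResult(
                        effect=f"{between} × {name_w}",
                        f_stat=f,
                        df_num=float(df_aw),
                        df_den=float(df_err),
                        p_value=p,
                        partial_eta2=eta,
                        ss_effect=ss_aw,
                        ss_error=ss_err,
                        gg_epsilon=eps,
                        corrected=corrected,
                        sphericity_w=w_stat,
                        sphericity_p=w_p,
                    )
                )
    return results


def mauchly_test(
    data: pd.DataFrame,
    factor: str,
    dv: str = "value",
    subject: str = DEFAULT_SUBJECT,
    between: str | None = None,
) -> tuple[float, float, float]:
    """Mauchly's sphericity test and Greenhouse–Geisser epsilon for one
    within factor.

    Other within factors present in the table are collapsed by averaging.
    For a 2-level factor sphericity holds trivially: returns (1, 1, 1).
    Raises :class:`RankDeficiencyError` with fewer subjects than levels or
    zero-variance data.
    """
    if between is not None and between in data.columns:
        gmap = data.groupby(subject)[between].first()
    else:
        gmap = None
    wide = data.pivot_table(index=subject, columns=factor, values=dv, aggfunc="mean")
    if wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)].tolist()
        raise IncompleteDesignError(f"subjects missing {factor} levels: {bad}")
    n_levels = wide.shape[1]
    if n_levels < 2:
        raise ValidationError(f"factor {factor!r} needs >= 2 levels")
    if n_levels == 2:
        return 1.0, 1.0, 1.0
    z = wide.to_numpy(dtype=float) @ _orthonormal_contrasts(n_levels)
    if gmap is not None:
        glab = gmap.reindex(wide.index)
        codes = pd.Categorical(glab).codes.astype(int)
    else:
        codes = np.zeros(len(wide), dtype=int)
    return _sphericity_from_scores(z, codes)


def tukey_posthoc(
    data: pd.DataFrame,
    effect: str,
    dv: str = "value",
    subject: str = DEFAULT_SUBJECT,
    between: str | None = DEFAULT_BETWEEN,
) -> pd.DataFrame:
    """All pairwise comparisons of one factor's levels, Tukey-style.

    For the between factor the error term is the subjects-within-groups
    mean square on subject means (Tukey–Kramer for unequal group sizes);
    for a within factor it is the factor-by-subject interaction mean square,
    the error stratum of the matching ANOVA effect.  Returns a table with
    the mean difference, studentized-range statistic and p-value per pair.
    """
    if effect == between:
        s = data.groupby(subject)[dv].mean()
        glab = data.groupby(subject)[between].first().reindex(s.index)
        levels = sorted(pd.unique(glab).tolist())
        if len(levels) < 2:
            raise ValidationError(f"effect {effect!r} has fewer than 2 levels")
        means = {g: s[glab == g].mean() for g in levels}
        ns = {g: int((glab == g).sum()) for g in levels}
        ss_w = sum(((s[glab == g] - means[g]) ** 2).sum() for g in levels)
        df_err = len(s) - len(levels)
        ms_err = ss_w / df_err
        rows = []
        for a, b in itertools.combinations(levels, 2):
            diff = means[a] - means[b]
            se = math.sqrt(ms_err / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
            q = abs(diff) / se if se > 0 else math.inf
            p = float(sps.studentized_range.sf(q, len(levels), df_err))
            rows.append(
                dict(level_a=a, level_b=b, diff=diff, q=q, p_value=p, df=df_err)
            )
        return pd.DataFrame(rows)

    if effect not in data.columns:
        raise ValidationError(f"unknown effect {effect!r}")
    wide = data.pivot_table(index=subject, columns=effect, values=dv, aggfunc="mean")
    levels = list(wide.columns)
    if len(levels) < 2:
        raise ValidationError(f"effect {effect!r} has fewer than 2 levels")
    y = wide.to_numpy(dtype=float)
    n = len(wide)
    if between is not None and between in data.columns:
        glab = data.groupby(subject)[between].first().reindex(wide.index)
        codes = pd.Categorical(glab).codes.astype(int)
    else:
        codes = np.zeros(n, dtype=int)
    g_levels = np.unique(codes)
    # interaction residuals: remove subject means and group-level profiles
    resid = y - y.mean(axis=1, keepdims=True)
    for g in g_levels:
        sel = codes == g
        prof = resid[sel].mean(axis=0)
        resid[sel] -= prof
    df_err = (n - len(g_levels)) * (len(levels) - 1)
    ms_err = float((resid**2).sum()) / df_err
    level_means = y.mean(axis=0)
    rows = []
    for i, j in itertools.combinations(range(len(levels)), 2):
        diff = level_means[i] - level_means[j]
        se = math.sqrt(ms_err / n)
        q = abs(diff) / se if se > 0 else math.inf
        p = float(sps.studentized_range.sf(q, len(levels), df_err))
        rows.append(
            dict(
                level_a=levels[i],
                level_b=levels[j],
                diff=diff,
                q=q,
                p_value=p,
                df=df_err,
            )
        )
    return pd.DataFrame(rows)


def one_way_anova(values, groups) -> AnovaResult:
    """One-way between-subjects ANOVA with partial eta-squared.

    ``values`` is one observation per subject; ``groups`` the group label of
    each.  Used for subject-level variables (anthropometry, strength
    indices) that carry no within-subject structure.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValidationError("need at least 2 groups")
    scale = float(((values - values.mean()) ** 2).sum())
    ss_b = 0.0
    ss_w = 0.0
    for g in levels:
        v = values[groups == g]
        if len(v) < 1:
            continue
        ss_b += len(v) * (v.mean() - values.mean()) ** 2
        ss_w += ((v - v.mean()) ** 2).sum()
    df_b = len(levels) - 1
    df_w = len(values) - len(levels)
    f, p, eta = _f_test(ss_b, df_b, ss_w, df_w, scale)
    return AnovaResult(
        effect="group",
        f_stat=f,
        df_num=float(df_b),
        df_den=float(df_w),
        p_value=p,
        partial_eta2=eta,
        ss_effect=ss_b,
        ss_error=ss_w,
    )


def pearson_corr(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("series lengths differ")
    if len(x) < 3:
        raise ValidationError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("non-finite values in input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in a series")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def linfit(x, y) -> tuple[float, float, float]:
    """Ordinary least squares y = a + b x; returns (a, b, r_squared)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("series lengths differ")
    if len(x) < 2:
        raise ValidationError("need at least 2 observations")
    if np.ptp(x) == 0:
        raise ValidationError("x is constant; slope undefined")
    res = sps.linregress(x, y)
    return float(res.intercept), float(res.slope), float(res.rvalue**2)
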