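"""Group-level statistics for microstate parameters.

The battery mirrors the standard analysis of a two-group microstate study:
2 (group) x 4 (class) mixed ANOVAs with Greenhouse-Geisser correction for
each temporal metric, per-class simple-effects t-tests, Bonferroni-corrected
two-sample t-tests on the 12 transition percentages, a chi-square test on
the sex table, pooled t-tests from printed summary statistics, and Pearson
correlations with clinical scores.  All t-tests are pooled-variance
(Student) and two-sided; the printed degrees of freedom (N1+N2-2) identify
that convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "TTestResult",
    "CorrelationResult",
    "ChiSqResult",
    "mixed_anova",
    "simple_effects",
    "transition_tests",
    "t_from_summary",
    "chi_square_2x2",
    "pearson_correlation",
    "gg_epsilon",
]


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df1: float
    df2: float
    epsilon_gg: float
    p_uncorrected: float
    p_gg: float
    sphericity_violated: bool | None = None


@dataclass(frozen=True)
class TTestResult:
    comparison: str
    t: float
    df: float
    p_raw: float
    p_bonferroni: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float


@dataclass(frozen=True)
class ChiSqResult:
    chi2: float
    df: int
    p: float
    yates: bool


def gg_epsilon(wide: np.ndarray, center_groups: np.ndarray | None = None) -> float:
    """Greenhouse-Geisser epsilon from the pooled within-subject covariance.

    ``wide`` is subjects x k repeated measures; when ``center_groups`` is
    given, each group's means are removed first so the covariance pools the
    within-group variation only (the mixed-design convention).
    """
    x = np.asarray(wide, dtype=float)
    if center_groups is not None:
        x = x.copy()
        for g in np.unique(center_groups):
            sel = center_groups == g
            x[sel] -= x[sel].mean(axis=0, keepdims=True)
    k = x.shape[1]
    s = np.cov(x, rowvar=False)
    # double-center and use the eigenvalue form of the GG estimator
    s_dc = s - s.mean(axis=0, keepdims=True) - s.mean(axis=1, keepdims=True) + s.mean()
    lam = np.linalg.eigvalsh(s_dc)
    lam = np.clip(lam, 0, None)
    num = lam.sum() ** 2
    den = (k - 1) * np.sum(lam**2)
    if den == 0:
        return 1.0
    return float(min(1.0, num / den))


def _long_table(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    cols = {"subject_id", "group", "class", metric}
    missing = cols - set(table.columns)
    if missing:
        raise ValueError(f"parameter table lacks columns {sorted(missing)}")
    long = table[["subject_id", "group", "class", metric]].rename(
        columns={metric: "value"}
    )
    counts = long.groupby("subject_id")["class"].nunique()
    if long["value"].isna().any() or counts.nunique() != 1:
        raise ValueError("every subject needs a value for every class")
    return long


def mixed_anova(table: pd.DataFrame, metric: str) -> list[AnovaResult]:
    """2-group x k-class mixed ANOVA with Greenhouse-Geisser correction.

    ``table`` is tidy: subject_id, group, class, plus the metric column
    (one of duration_ms / occurrence_hz / coverage_pct).  Returns the
    between-group, within-class and interaction effects; the GG-corrected
    p is always reported, with a Mauchly test (alpha = 0.05) flagging
    whether sphericity is violated.
    """
    long = _long_table(table, metric)
    aov = pg.mixed_anova(
        data=long,
        dv="value",
        within="class",
        subject="subject_id",
        between="group",
        correction=True,
    )
    wide = long.pivot(index="subject_id", columns="class", values="value")
    groups = long.drop_duplicates("subject_id").set_index("subject_id")["group"]
    groups = groups.loc[wide.index].to_numpy()
    eps = gg_epsilon(wide.to_numpy(), center_groups=groups)

    centered = wide.to_numpy().copy()
    for g in np.unique(groups):
        centered[groups == g] -= centered[groups == g].mean(axis=0, keepdims=True)
    spher_stat = pd.DataFrame(
        centered, columns=wide.columns, index=wide.index
    ).reset_index().melt(id_vars="subject_id", var_name="class", value_name="value")
    spher = pg.sphericity(
        data=spher_stat, dv="value", within="class", subject="subject_id"
    )
    violated = bool(spher.pval < 0.05)

    out = []
    for _, row in aov.iterrows():
        effect = {"group": "group", "class": "class", "Interaction": "interaction"}[
            row["Source"]
        ]
        f, df1, df2 = float(row["F"]), float(row["DF1"]), float(row["DF2"])
        p_unc = float(row["p_unc"])
        if effect == "group":
            e, p_gg, viol = float("nan"), p_unc, None
        else:
            e = eps
            p_gg = float(sps.f.sf(f, e * df1, e * df2))
            viol = violated
        out.append(
            AnovaResult(
                effect=effect,
                F=f,
                df1=df1,
                df2=df2,
                epsilon_gg=e,
                p_uncorrected=p_unc,
                p_gg=p_gg,
                sphericity_violated=viol,
            )
        )
    return out


def _pooled_t(x1: np.ndarray, x2: np.ndarray, label: str, m: int = 1) -> TTestResult:
    res = sps.ttest_ind(x1, x2, equal_var=True)
    df = len(x1) + len(x2) - 2
    p = float(res.pvalue)
    return TTestResult(
        comparison=label,
        t=float(res.statistic),
        df=df,
        p_raw=p,
        p_bonferroni=min(1.0, m * p),
    )


def simple_effects(
    table: pd.DataFrame, metric: str, group_order: tuple[str, str] | None = None
) -> list[TTestResult]:
    """Per-class pooled two-sample t-tests between the two groups."""
    long = _long_table(table, metric)
    groups = sorted(long["group"].unique()) if group_order is None else list(group_order)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    out = []
    for cls, sub in long.groupby("class", sort=True):
        x1 = sub.loc[sub["group"] == groups[0], "value"].to_numpy()
        x2 = sub.loc[sub["group"] == groups[1], "value"].to_numpy()
        if len(x1) == 0 or len(x2) == 0:
            raise ValueError(f"class {cls} missing in one group")
        out.append(_pooled_t(x1, x2, f"{metric}[{cls}]: {groups[0]} vs {groups[1]}"))
    return out


def transition_tests(
    table: pd.DataFrame, group_order: tuple[str, str] | None = None
) -> list[TTestResult]:
    """Bonferroni-corrected (m=12) group tests on each transition percentage.

    ``table`` is tidy: subject_id, group, transition, percent.  A transition
    constant across all subjects yields an undefined t, reported as NaN.
    """
    need = {"subject_id", "group", "transition", "percent"}
    if need - set(table.columns):
        raise ValueError("transition table lacks required columns")
    groups = sorted(table["group"].unique()) if group_order is None else list(group_order)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    if table.groupby("subject_id")["transition"].nunique().nunique() != 1:
        raise ValueError("every subject needs all transitions")
    out = []
    for tr, sub in table.groupby("transition", sort=True):
        x1 = sub.loc[sub["group"] == groups[0], "percent"].to_numpy()
        x2 = sub.loc[sub["group"] == groups[1], "percent"].to_numpy()
        if np.std(np.concatenate([x1, x2])) == 0:
            out.append(
                TTestResult(f"{tr}: {groups[0]} vs {groups[1]}",
                            float("nan"), len(x1) + len(x2) - 2,
                            float("nan"), float("nan"))
            )
            continue
        out.append(_pooled_t(x1, x2, f"{tr}: {groups[0]} vs {groups[1]}", m=12))
    return out


def t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    label: str = "",
) -> TTestResult:
    """Pooled-variance two-sample t from printed summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    p = float(res.pvalue)
    return TTestResult(label, float(res.statistic), n1 + n2 - 2, p, p)


def chi_square_2x2(counts: np.ndarray, yates: bool = True) -> ChiSqResult:
    """Pearson chi-square on a 2x2 table, optional Yates correction."""
    counts = np.asarray(counts)
    if counts.shape != (2, 2) or np.any(counts < 0):
        raise ValueError("counts must be a non-negative 2x2 table")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("zero marginal total")
    chi2, p, dof, _ = sps.chi2_contingency(counts, correction=yates)
    return ChiSqResult(chi2=float(chi2), df=int(dof), p=float(p), yates=yates)


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Pearson r with the two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-D arrays, n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(r=float(r), n=len(x), p=float(p))
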