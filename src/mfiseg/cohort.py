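"""Cohort-level MFI characterisation statistics.

Operates on a per-subject table with one row per subject: sex, age (years),
BMI (kg/m²) and one bilaterally-averaged MFI column per muscle group.  The
analyses mirror the standard exploratory battery for muscle-composition
cohorts:

* pairwise two-tailed paired t-tests of MFI between muscle groups;
* one-way ANCOVA per group — the linear model ``MFI ~ sex + age + BMI``
  with sex a fixed factor (female = 1, so a positive coefficient means
  higher MFI in females) and estimated marginal means at the covariate
  means;
* two-tailed partial Pearson correlations (e.g. MFI vs age controlling for
  sex and BMI) via residual regression;
* a repeated-measures ANCOVA with muscle group as the within-subject
  factor, sex between subjects, and age and BMI as covariates, with
  Greenhouse-Geisser correction of the within-subject degrees of freedom.

No multiple-comparison correction is applied anywhere: the battery is
exploratory and the p values are reported raw.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SexAncovaResult",
    "RmAncovaResult",
    "paired_group_tests",
    "sex_ancova",
    "partial_corr",
    "rm_ancova",
]


def _group_columns(table: pd.DataFrame, groups=None) -> list[str]:
    reserved = {"subject_id", "sex", "age", "bmi"}
    if groups is None:
        groups = [c for c in table.columns if c not in reserved]
    if len(groups) < 1:
        raise ValueError("no muscle-group MFI columns found")
    return list(groups)


def _sex_indicator(table: pd.DataFrame) -> np.ndarray:
    sex = table["sex"].astype(str).str.upper().str[0]
    if not set(sex) <= {"F", "M"}:
        raise ValueError("sex column must contain only F/M values")
    return (sex == "F").to_numpy(dtype=float)


# ------------------------------------------------------------- paired tests
def paired_group_tests(table: pd.DataFrame, groups=None) -> pd.DataFrame:
    """Two-tailed paired t-tests of MFI between every pair of muscle groups.

    Returns one row per unordered pair with the mean difference (a − b),
    t statistic, degrees of freedom and raw p value.  Pairs whose
    differences have zero variance are flagged (``nan`` t/p) rather than
    raising.
    """
    groups = _group_columns(table, groups)
    if len(groups) < 2:
        raise ValueError("need at least two muscle groups")
    if len(table) < 3:
        raise ValueError("need at least three subjects")
    rows = []
    for a, b in itertools.combinations(groups, 2):
        d = table[a].to_numpy(dtype=float) - table[b].to_numpy(dtype=float)
        row = {
            "group_a": a,
            "group_b": b,
            "mean_diff": float(d.mean()),
            "df": len(d) - 1,
        }
        if d.std(ddof=1) == 0:
            # degenerate: identical columns carry no evidence of a difference
            # (t = 0, p = 1); a constant nonzero offset has an infinite t
            # statistic, which we flag rather than fabricate
            if d.mean() == 0:
                row.update(t=0.0, p=1.0, flags="zero_variance")
            else:
                row.update(t=math.nan, p=math.nan, flags="zero_variance")
        else:
            t, p = stats.ttest_rel(table[a], table[b])
            row.update(t=float(t), p=float(p), flags="")
        rows.append(row)
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ ANCOVA
@dataclass(frozen=True)
class SexAncovaResult:
    """One-way ANCOVA of MFI on sex with age and BMI covariates."""

    group: str
    sex_effect: float       # female minus male, adjusted
    se: float
    ci_low: float
    ci_high: float
    f: float
    p: float
    emm_female: float       # marginal means at covariate means
    emm_male: float
    n: int

    def as_dict(self) -> dict:
        return asdict(self)


def sex_ancova(table: pd.DataFrame, group: str) -> SexAncovaResult:
    """Linear model ``MFI ~ sex + age + BMI`` for one muscle group.

    Sex is coded female = 1 / male = 0, so ``sex_effect`` is the adjusted
    female excess in MFI percentage points.  The F statistic for the sex
    term equals t² on (1, n − 4) df.  Estimated marginal means evaluate the
    fit at the sample covariate means for each sex.
    """
    female = _sex_indicator(table)
    if female.min() == female.max():
        raise ValueError("both sexes must be present for an ANCOVA")
    y = table[group].to_numpy(dtype=float)
    age = table["age"].to_numpy(dtype=float)
    bmi = table["bmi"].to_numpy(dtype=float)
    n = len(y)
    # constant covariates carry no information; dropping them makes the
    # model reduce exactly to a two-sample t-test (F = t^2)
    covs = [c for c in (age, bmi) if c.std() > 0]
    x = np.column_stack([np.ones(n), female] + covs)
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < x.shape[1]:
        raise ValueError("design matrix is rank deficient")
    resid = y - x @ beta
    df_e = n - x.shape[1]
    sigma2 = float(resid @ resid) / df_e
    cov = sigma2 * np.linalg.inv(x.T @ x)
    se = math.sqrt(cov[1, 1])
    t = beta[1] / se
    p = 2.0 * float(stats.t.sf(abs(t), df_e))
    tcrit = float(stats.t.ppf(0.975, df_e))
    adjust = sum(b * c.mean() for b, c in zip(beta[2:], covs))
    emm_f = float(beta[0] + beta[1] + adjust)
    emm_m = float(beta[0] + adjust)
    return SexAncovaResult(
        group=group,
        sex_effect=float(beta[1]),
        se=se,
        ci_low=float(beta[1] - tcrit * se),
        ci_high=float(beta[1] + tcrit * se),
        f=float(t * t),
        p=p,
        emm_female=emm_f,
        emm_male=emm_m,
        n=n,
    )


# ------------------------------------------------------------ partial corr
def partial_corr(x, y, controls=None):
    """Two-tailed partial Pearson correlation of x and y given controls.

    Both variables are regressed (with intercept) on the control matrix and
    the Pearson correlation of the residuals is returned with its p value
    from the t transform on ``n − k − 2`` df (k = number of controls).
    With no controls this is the plain Pearson correlation.  Collinear
    controls raise.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if controls is None or (hasattr(controls, "__len__") and len(controls) == 0):
        z = np.ones((n, 1))
        k = 0
    else:
        c = np.asarray(controls, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        if c.shape[0] != n:
            raise ValueError("controls must have one row per observation")
        z = np.column_stack([np.ones(n), c])
        k = c.shape[1]
        if np.linalg.matrix_rank(z) < z.shape[1]:
            raise ValueError("collinear controls")
    df = n - k - 2
    if df < 1:
        raise ValueError(f"need more than {k + 2} observations for {k} controls")
    rx = x - z @ np.linalg.lstsq(z, x, rcond=None)[0]
    ry = y - z @ np.linalg.lstsq(z, y, rcond=None)[0]
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        return math.nan, math.nan
    r = float(rx @ ry) / denom
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt(df / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return r, p


# --------------------------------------------------------------- rm-ANCOVA
@dataclass(frozen=True)
class RmAncovaResult:
    """Repeated-measures ANCOVA summary.

    Within-subject tests (muscle group and group x sex) use the univariate
    approach on orthonormal within-subject contrasts with
    Greenhouse-Geisser corrected degrees of freedom; the between-subject
    sex test is an ANCOVA on the subject means.
    """

    f_group: float
    df1_group: float
    df2_group: float
    p_group: float
    f_group_sex: float
    p_group_sex: float
    f_sex: float
    df1_sex: float
    df2_sex: float
    p_sex: float
    gg_epsilon: float
    n: int

    def as_dict(self) -> dict:
        return asdict(self)


def _helmert_orthonormal(g: int) -> np.ndarray:
    """g x (g-1) orthonormal within-subject contrast matrix."""
    c = np.zeros((g, g - 1))
    for j in range(1, g):
        c[:j, j - 1] = 1.0 / j
        c[j, j - 1] = -1.0
        c[:, j - 1] /= np.linalg.norm(c[:, j - 1])
    return c


def rm_ancova(
    table: pd.DataFrame,
    groups=None,
    between: tuple[str, ...] = ("sex",),
    covariates: tuple[str, ...] = ("age", "bmi"),
) -> RmAncovaResult:
    """Repeated-measures ANCOVA of MFI across muscle groups.

    Within-subject factor: muscle group; between-subject factor: sex;
    covariates: age and BMI (mean-centred).  Rows with any missing group
    value are excluded with a warning.  Sphericity is handled by the
    Greenhouse-Geisser epsilon estimated from the residual covariance of
    the orthonormal contrast variables; both within-subject F tests report
    epsilon-corrected degrees of freedom.

    With ``between=()`` and ``covariates=()`` the between design reduces to
    the intercept and the group test is the classical one-way
    repeated-measures ANOVA (the group-by-sex test is then reported as
    ``nan``).
    """
    groups = _group_columns(table, groups)
    g = len(groups)
    if g < 2:
        raise ValueError("need at least two muscle groups")
    needed = groups + list(covariates) + (["sex"] if "sex" in between else [])
    complete = table.dropna(subset=needed)
    dropped = len(table) - len(complete)
    if dropped:
        import warnings

        warnings.warn(
            f"excluded {dropped} subjects with incomplete data", UserWarning, stacklevel=2
        )
    n = len(complete)
    if n < 6:
        raise ValueError("need at least six complete subjects")
    y = complete[groups].to_numpy(dtype=float)

    # between-subject design: intercept, sex indicator, centred covariates
    cols = [np.ones(n)]
    sex_row = None
    if "sex" in between:
        cols.append(_sex_indicator(complete))
        sex_row = 1
    for cov in covariates:
        v = complete[cov].to_numpy(dtype=float)
        cols.append(v - v.mean())
    x = np.column_stack(cols)
    p_cols = x.shape[1]
    df_e = n - p_cols
    xtx_inv = np.linalg.inv(x.T @ x)
    hat = x @ xtx_inv @ x.T

    # within-subject contrast variables
    c = _helmert_orthonormal(g)
    z = y @ c                       # n x (g-1)
    b = xtx_inv @ x.T @ z           # p x (g-1)
    e = z.T @ (np.eye(n) - hat) @ z  # residual SSCP, (g-1) x (g-1)

    def within_test(row: int):
        l = np.zeros((1, p_cols))
        l[0, row] = 1.0
        lb = l @ b
        h = lb.T @ np.linalg.inv(l @ xtx_inv @ l.T) @ lb
        f = (np.trace(h) / (g - 1)) / (np.trace(e) / ((g - 1) * df_e))
        return float(f)

    sigma = e / df_e
    tr = float(np.trace(sigma))
    tr2 = float(np.trace(sigma @ sigma))
    eps = tr**2 / ((g - 1) * tr2) if tr2 > 0 else 1.0
    eps = min(1.0, max(1.0 / (g - 1), eps))

    f_group = within_test(0)        # intercept row: group effect at covariate means
    df1 = eps * (g - 1)
    df2 = eps * (g - 1) * df_e
    p_group = float(stats.f.sf(f_group, df1, df2))
    if sex_row is not None:
        f_group_sex = within_test(sex_row)  # group x sex interaction
        p_group_sex = float(stats.f.sf(f_group_sex, df1, df2))
    else:
        f_group_sex = p_group_sex = math.nan

    # between-subject sex effect on the subject means
    if sex_row is not None:
        ybar = y.mean(axis=1)
        beta = xtx_inv @ x.T @ ybar
        resid = ybar - x @ beta
        mse = float(resid @ resid) / df_e
        se = math.sqrt(mse * xtx_inv[sex_row, sex_row])
        f_sex = float((beta[sex_row] / se) ** 2) if se > 0 else math.nan
        p_sex = float(stats.f.sf(f_sex, 1, df_e)) if not math.isnan(f_sex) else math.nan
    else:
        f_sex = p_sex = math.nan

    return RmAncovaResult(
        f_group=f_group,
        df1_group=float(df1),
        df2_group=float(df2),
        p_group=p_group,
        f_group_sex=f_group_sex,
        p_group_sex=p_group_sex,
        f_sex=f_sex,
        df1_sex=1.0,
        df2_sex=float(df_e),
        p_sex=p_sex,
        gg_epsilon=float(eps),
        n=n,
    )
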