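"""Accuracy and reliability battery for paired measurement series.

Given per-scan measures from two sources — typically a reference (ground
truth, GT) and a test method (CNN output, or a second human rater) — this
module computes the standard method-comparison battery:

* Bland-Altman bias and 95% limits of agreement (bias ± 1.96 x SD of the
  paired differences, sample SD), plus mean absolute error and root mean
  squared error;
* squared Pearson correlation r² and the regression-through-origin
  coefficient β of the reference on the test measure (GT ≈ β·test), which
  can be used to correct a proportional bias in the test method;
* the intraclass correlation ICC(2,1) — two-way random effects, absolute
  agreement, single measure (Shrout-Fleiss) — with its F-test p value and
  the McGraw-Wong F-based confidence interval.

Differences are oriented test − reference throughout, so a positive bias
means the test method over-reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgreementReport",
    "bland_altman",
    "accuracy_summary",
    "icc_2_1",
    "agreement_report",
    "reliability_report",
]


@dataclass(frozen=True)
class AgreementReport:
    """Full agreement summary for one paired series."""

    bias: float
    loa_low: float
    loa_high: float
    mae: float
    rmse: float
    r2: float
    beta_origin: float
    icc21: float
    icc_ci_low: float
    icc_ci_high: float
    icc_p: float
    n: int

    def as_dict(self) -> dict:
        return asdict(self)


def _paired(reference, test):
    r = np.asarray(reference, dtype=float).ravel()
    t = np.asarray(test, dtype=float).ravel()
    if r.shape != t.shape:
        raise ValueError(f"length mismatch: reference {r.size} vs test {t.size}")
    if np.isnan(r).any() or np.isnan(t).any():
        raise ValueError("paired series contain undefined entries; filter first")
    if r.size < 2:
        raise ValueError("need at least 2 pairs")
    return r, t


def bland_altman(reference, test):
    """Bias, 95% limits of agreement, MAE and RMSE of test − reference.

    Returns ``(bias, loa_low, loa_high, mae, rmse)``.  The limits use the
    sample (n−1) standard deviation of the differences.
    """
    r, t = _paired(reference, test)
    d = t - r
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    mae = float(np.abs(d).mean())
    rmse = float(np.sqrt((d**2).mean()))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd, mae, rmse


def accuracy_summary(reference, test):
    """Squared Pearson r and through-origin slope of reference on test.

    β minimises ||reference − β·test||², i.e. β = Σ(t·r)/Σ(t²); multiplying
    the test measure by β gives the least-squares bias-corrected estimate of
    the reference.  r² is ``nan`` when either series is constant.
    """
    r, t = _paired(reference, test)
    denom = float((t**2).sum())
    beta = float((t * r).sum() / denom) if denom > 0 else math.nan
    if r.std() == 0 or t.std() == 0:
        r2 = math.nan
    else:
        r2 = float(np.corrcoef(r, t)[0, 1] ** 2)
    return r2, beta


def icc_2_1(values, alpha: float = 0.05):
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``values`` is an (n subjects x k raters) complete table.  Returns
    ``(icc, ci_low, ci_high, p)`` with the McGraw-Wong F-based
    ``1 - alpha`` confidence interval and the p value of the F-test of the
    null ICC = 0 (F = MSR/MSE on (n−1, (n−1)(k−1)) df).

    From the two-way ANOVA mean squares (rows = subjects, columns = raters):

        ICC(2,1) = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n)

    Raises on an incomplete table (no imputation); returns ``nan`` for the
    degenerate all-constant table.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 2:
        raise ValueError(f"values must be a 2D subjects x raters table, got {y.shape}")
    n, k = y.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    if np.isnan(y).any():
        raise ValueError("incomplete table: remove subjects with missing ratings")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")

    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((y - grand) ** 2).sum())
    sse = max(sst - ssr - ssc, 0.0)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if msr == 0.0 and mse == 0.0:
        return math.nan, math.nan, math.nan, math.nan
    icc = (msr - mse) / denom if denom != 0 else math.nan

    # F-test of ICC = 0
    if mse > 0:
        f_obs = msr / mse
        p = float(stats.f.sf(f_obs, n - 1, (n - 1) * (k - 1)))
    else:
        p = 0.0 if msr > 0 else math.nan

    # McGraw-Wong CI via Satterthwaite df
    if math.isnan(icc) or icc >= 1.0 or mse == 0.0:
        return icc, math.nan if math.isnan(icc) else icc, icc, p
    r = icc
    a = k * r / (n * (1.0 - r))
    b = 1.0 + k * r * (n - 1) / (n * (1.0 - r))
    num_v = (a * msc + b * mse) ** 2
    den_v = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num_v / den_v if den_v > 0 else float((n - 1) * (k - 1))
    f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    ci_low = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    ci_high = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return float(icc), float(ci_low), float(ci_high), p


def agreement_report(reference, test, alpha: float = 0.05) -> AgreementReport:
    """All agreement statistics for one paired series (test vs reference)."""
    r, t = _paired(reference, test)
    bias, lo, hi, mae, rmse = bland_altman(r, t)
    r2, beta = accuracy_summary(r, t)
    icc, ci_l, ci_h, p = icc_2_1(np.column_stack([r, t]), alpha=alpha)
    return AgreementReport(
        bias=bias,
        loa_low=lo,
        loa_high=hi,
        mae=mae,
        rmse=rmse,
        r2=r2,
        beta_origin=beta,
        icc21=icc,
        icc_ci_low=ci_l,
        icc_ci_high=ci_h,
        icc_p=p,
        n=int(r.size),
    )


def reliability_report(
    measures_ref: pd.DataFrame,
    measures_test: pd.DataFrame,
    measures: tuple[str, ...] = ("mfi_percent", "volume_ml"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-muscle agreement battery between two per-scan measure tables.

    Both inputs are tables as produced by ``measure_all`` with a ``scan_id``
    column (one row per scan x label).  Rows are matched on
    ``(scan_id, label)``; unmatched rows raise an error listing the
    offenders.  Pairs where either side is undefined (``nan``) are dropped
    per measure.  Returns one row per (label, measure) with the full
    :class:`AgreementReport` columns.
    """
    key = ["scan_id", "label"]
    for name, df in (("reference", measures_ref), ("test", measures_test)):
        missing = [c for c in key if c not in df.columns]
        if missing:
            raise ValueError(f"{name} table lacks key columns {missing}")
    merged = measures_ref.merge(
        measures_test, on=key, how="outer", suffixes=("_ref", "_test"), indicator=True
    )
    bad = merged[merged["_merge"] != "both"]
    if len(bad):
        offenders = bad[key + ["_merge"]].to_dict("records")
        raise ValueError(f"unmatched scan/label rows: {offenders[:10]}")

    rows = []
    for label, sub in merged.groupby("label"):
        group = sub["group_ref"].iloc[0] if "group_ref" in sub else ""
        side = sub["side_ref"].iloc[0] if "side_ref" in sub else ""
        for measure in measures:
            a = sub[f"{measure}_ref"].to_numpy(dtype=float)
            b = sub[f"{measure}_test"].to_numpy(dtype=float)
            ok = ~(np.isnan(a) | np.isnan(b))
            row = {
                "label": label,
                "group": group,
                "side": side,
                "measure": measure,
            }
            if ok.sum() >= 2:
                row.update(agreement_report(a[ok], b[ok], alpha=alpha).as_dict())
            else:
                row.update({k: math.nan for k in AgreementReport.__dataclass_fields__})
                row["n"] = int(ok.sum())
            rows.append(row)
    return pd.DataFrame(rows)
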