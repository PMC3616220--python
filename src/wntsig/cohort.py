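"""IHC-cohort analytics: ordinal scores, dichotomization, survival scan.

The brain-metastasis cohort carries per-patient ordinal immunohistochemistry
scores — nuclear LEF1 and beta-catenin on a 0-3+ scale (0 %, 1-25 %, 25-50 %,
>50 % positive nuclei), nuclear TCF4 on a 0-4+ scale (0 %, 1-33 %, 33-66 %,
66-99 %, >99 %), the Ki67 proliferation index in percent, and an opaque
numeric TTF1 score — plus clinical binaries, age, and right-censored overall
survival since brain-metastasis diagnosis.

Markers are dichotomized with the study cuts (Ki67 high >= 10 %, TTF1
positive > 3, LEF1 positive >= 1+, TCF4 top bin = 4+, beta-catenin positive
>= 1+, and the combined LEF1+/TCF4(4+) stratum), correlated pairwise by
Pearson on the numeric codes, and each binary parameter is scanned
univariately with a Cox fit and a log-rank test, mirroring a baseline
characteristics table.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .signature import PearsonResult, pearson_r
from .survival import (
    NonConvergenceError,
    SurvivalRecord,
    cox_fit,
    logrank_test,
)

logger = logging.getLogger(__name__)

__all__ = [
    "validate_cohort",
    "read_cohort_tsv",
    "dichotomize",
    "marker_correlation",
    "univariate_scan",
    "MARKER_COLUMNS",
]

MARKER_COLUMNS = ["lef1", "tcf4", "beta_catenin", "ki67_percent", "ttf1_score"]

_SCORE_RANGES = {"lef1": (0, 3), "tcf4": (0, 4), "beta_catenin": (0, 3)}


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Check CohortTable invariants; returns the frame unchanged."""
    if "patient_id" not in df.columns:
        raise ValueError("cohort table needs a patient_id column")
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ValueError(f"duplicate patient id: {dup!r}")
    for col, (lo, hi) in _SCORE_RANGES.items():
        if col in df.columns:
            vals = df[col].dropna()
            if ((vals < lo) | (vals > hi) | (vals != vals.round())).any():
                raise ValueError(f"{col}: scores must be integers in [{lo},{hi}]")
    if "ki67_percent" in df.columns:
        vals = df["ki67_percent"].dropna()
        if ((vals < 0) | (vals > 100)).any():
            raise ValueError("ki67_percent must lie in [0,100]")
    if {"time_months", "event"} <= set(df.columns):
        if (df["time_months"] < 0).any() or not np.isfinite(df["time_months"]).all():
            raise ValueError("time_months must be finite and >= 0")
        if not df["event"].isin([0, 1]).all():
            raise ValueError("event must be 0/1")
    return df


def read_cohort_tsv(path) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path, sep="\t"))


def dichotomize(df: pd.DataFrame, ki67_cut: float = 10.0,
                ki67_strict: bool = False) -> pd.DataFrame:
    """Binary marker columns from ordinal/continuous scores.

    Cuts: ki67_high = (ki67_percent >= ki67_cut) — or strictly greater with
    ``ki67_strict=True``; ttf1_positive = (ttf1_score > 3); lef1_positive =
    (lef1 >= 1); tcf4_top = (tcf4 == 4); beta_catenin_positive =
    (beta_catenin >= 1); lef1_tcf4_combined = lef1_positive AND tcf4_top.
    Missing scores propagate as NA and are excluded per-marker downstream
    (counts logged).
    """
    validate_cohort(df)
    out = df[["patient_id"]].copy()

    def _cut(col, fn):
        if col not in df.columns:
            return pd.Series(pd.NA, index=df.index, dtype="boolean")
        vals = df[col]
        res = pd.Series(pd.NA, index=df.index, dtype="boolean")
        ok = vals.notna()
        res[ok] = fn(vals[ok])
        n_miss = int((~ok).sum())
        if n_miss:
            logger.info("dichotomize: %d missing values in %s", n_miss, col)
        return res

    if ki67_strict:
        out["ki67_high"] = _cut("ki67_percent", lambda v: v > ki67_cut)
    else:
        out["ki67_high"] = _cut("ki67_percent", lambda v: v >= ki67_cut)
    out["ttf1_positive"] = _cut("ttf1_score", lambda v: v > 3)
    out["lef1_positive"] = _cut("lef1", lambda v: v >= 1)
    out["tcf4_top"] = _cut("tcf4", lambda v: v == 4)
    out["beta_catenin_positive"] = _cut("beta_catenin", lambda v: v >= 1)
    out["lef1_tcf4_combined"] = out["lef1_positive"] & out["tcf4_top"]
    return out


def marker_correlation(a, b) -> PearsonResult:
    """Pearson r (with p and Fisher-z CI) on paired marker codes.

    Accepts numeric, ordinal or binary codes; pairs with a missing value on
    either side are dropped (>= 3 complete pairs required).
    """
    a = pd.Series(a, dtype=float)
    b = pd.Series(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("vectors must be paired")
    ok = a.notna() & b.notna()
    if ok.sum() < 3:
        raise ValueError("need >= 3 complete pairs")
    return pearson_r(a[ok].to_numpy(), b[ok].to_numpy())


def _binary_parameters(df: pd.DataFrame, parameters: list[str]) -> pd.DataFrame:
    """Assemble the binary design columns, deriving markers and the age split."""
    marker_bins = dichotomize(df) if any(c in df.columns for c in MARKER_COLUMNS) \
        else pd.DataFrame({"patient_id": df["patient_id"]})
    design = pd.DataFrame(index=df.index)
    for p in parameters:
        if p in marker_bins.columns:
            design[p] = marker_bins[p].astype("Float64")
        elif p == "age_high":
            med = df["age"].median()
            design[p] = (df["age"] >= med).astype(float)
        elif p in df.columns:
            design[p] = pd.to_numeric(df[p], errors="coerce")
        else:
            raise KeyError(f"unknown parameter {p!r}")
    return design


def univariate_scan(df: pd.DataFrame, parameters: list[str]) -> pd.DataFrame:
    """Per-parameter univariate Cox HR (with Wald CI) and log-rank p.

    Each parameter must be binary after dichotomization; ``age_high`` splits
    age at the cohort median.  Parameters with a single observed level are
    skipped with a warning row (hr = NA).  Patients missing the parameter or
    survival data are excluded from that parameter's fit.
    """
    validate_cohort(df)
    design = _binary_parameters(df, parameters)
    rows = []
    for p in parameters:
        vals = design[p].astype(float)
        ok = vals.notna() & df["time_months"].notna() & df["event"].notna()
        sub = df[ok]
        v = vals[ok].to_numpy(dtype=float)
        n_pos = int((v == 1).sum())
        n_neg = int((v == 0).sum())
        if len(np.unique(v)) < 2 or sub["event"].sum() == 0:
            logger.warning("univariate_scan: %s has one level or no events; skipped", p)
            rows.append((p, n_pos, n_neg, np.nan, np.nan, np.nan, np.nan))
            continue
        records = [
            SurvivalRecord(str(pid), float(t), int(e), {p: float(x)})
            for pid, t, e, x in zip(
                sub["patient_id"], sub["time_months"], sub["event"], v
            )
        ]
        try:
            fit = cox_fit(records, [p])
            est = fit[p]
            hr, lo, hi = est["hr"], est["ci_low"], est["ci_high"]
        except NonConvergenceError:
            logger.warning("univariate_scan: Cox fit for %s did not converge", p)
            hr = lo = hi = np.nan
        grp1 = [r for r, x in zip(records, v) if x == 1]
        grp0 = [r for r, x in zip(records, v) if x == 0]
        _, logrank_p = logrank_test([grp1, grp0])
        rows.append((p, n_pos, n_neg, hr, lo, hi, logrank_p))
    return pd.DataFrame(
        rows,
        columns=["parameter", "n_positive", "n_negative",
                 "hr", "ci_low", "ci_high", "logrank_p"],
    )
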