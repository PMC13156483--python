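"""Univariate statistical battery for the measurement panel.

Welch two-tailed t-tests with FDR control (Benjamini-Hochberg or the
two-stage step-up), Cohen's d, percent change vs control, intraobserver
coefficient of variation, ICC(A,1) absolute-agreement reliability, and a
balanced two-way ANOVA for tabular staining ratios.

Convention: each experimental genotype is compared to control only. Comparing
the two experimental groups to one another requires an explicit override.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.multitest import multipletests

FDR_PROCEDURES = ("two-stage", "bh")


@dataclass
class GroupComparison:
    measurement: str
    group: str
    mean_exp: float
    sd_exp: float
    n_exp: int
    mean_ctrl: float
    sd_ctrl: float
    n_ctrl: int
    percent_change: float
    t: float
    df: float
    p: float
    q_discovery: bool
    cohens_d: float
    meaningful: bool  # FDR discovery AND p < stringent alpha
    degenerate: bool = False


@dataclass
class ReliabilityReport:
    measurement: str
    cv_percent: float
    replicable: bool  # CV < 10%


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unpaired two-tailed t-test: (t, Welch-Satterthwaite df, p).

    Two constant, equal samples degenerate to t = 0, p = 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("Welch t-test needs n >= 2 per group")
    # Samples constant to machine precision: differences at the 1-ulp level
    # (e.g. threaded-BLAS jitter on analytically identical specimens) are not
    # evidence; equal means degenerate to t = 0, p = 1, materially distinct
    # constant means to complete separation.
    scale = max(abs(x.mean()), abs(y.mean()), 1e-300)
    if x.std(ddof=1) <= 1e-12 * scale and y.std(ddof=1) <= 1e-12 * scale:
        if abs(x.mean() - y.mean()) <= 1e-9 * scale:
            return 0.0, float(len(x) + len(y) - 2), 1.0
        return float(np.inf * np.sign(x.mean() - y.mean())), float(len(x) + len(y) - 2), 0.0
    with np.errstate(all="ignore"):
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)
            res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def fdr_adjust(pvalues: Sequence[float], q: float = 5.0,
               procedure: str = "two-stage") -> tuple[np.ndarray, np.ndarray]:
    """Discovery flags (and adjusted values) controlling the FDR at Q percent.

    ``procedure``: ``"two-stage"`` (the two-stage step-up, the usual
    desktop-statistics default) or ``"bh"`` (plain Benjamini-Hochberg).
    """
    p = np.asarray(pvalues, float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 100:
        raise ValueError(f"Q must be a percentage in (0, 100), got {q}")
    if procedure not in FDR_PROCEDURES:
        raise ValueError(f"unknown FDR procedure {procedure!r}; choose from {FDR_PROCEDURES}")
    if p.size == 0:
        return np.zeros(0, bool), np.zeros(0)
    method = "fdr_tsbh" if procedure == "two-stage" else "fdr_bh"
    reject, adjusted, _, _ = multipletests(p, alpha=q / 100.0, method=method)
    return reject, adjusted


def cohens_d(x: Sequence[float], y: Sequence[float]) -> float:
    """Cohen's d with the pooled (n-1 weighted) standard deviation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("Cohen's d needs n >= 2 per group")
    nx, ny = len(x), len(y)
    pooled = math.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2))
    if pooled == 0:
        raise ValueError("Cohen's d undefined: zero pooled standard deviation")
    return float((x.mean() - y.mean()) / pooled)


def percent_change(mean_exp: float, mean_ctrl: float) -> float:
    if mean_ctrl == 0:
        raise ValueError("percent change undefined for a zero control mean")
    return (mean_exp - mean_ctrl) / mean_ctrl * 100.0


def intraobserver_cv(first: float, second: float) -> tuple[float, bool]:
    """CV (%) between two landmarking sessions: sample SD of the pair / pair mean x 100."""
    pair = np.array([first, second], float)
    if not np.all(np.isfinite(pair)):
        raise ValueError("intraobserver CV needs two finite values")
    mean = pair.mean()
    if mean == 0:
        raise ValueError("intraobserver CV undefined for a zero mean")
    cv = float(pair.std(ddof=1) / abs(mean) * 100.0)
    return cv, cv < 10.0


def icc_a1(ratings: np.ndarray, confidence: float = 0.95) -> tuple[float, float, float]:
    """ICC(A,1): two-way model, single rater, absolute agreement, with an F-based CI.

    ``ratings`` is an (n subjects x k raters) complete table.
    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)).
    """
    y = np.asarray(ratings, float)
    if y.ndim != 2 or y.shape[0] < 2 or y.shape[1] < 2:
        raise ValueError("ICC needs a complete n>=2 x k>=2 table")
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)       # between subjects
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)       # between raters
    sse = np.sum((y - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if msr <= mse and np.isclose(msr, 0):
        raise ValueError("ICC undefined: zero between-subject variance")
    icc = (msr - mse) / denom

    # Confidence interval for absolute agreement, single measures
    # (McGraw & Wong): F* based bounds.
    alpha = 1.0 - confidence
    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if not np.isfinite(a):
        return float(icc), 1.0, 1.0
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
    f_low = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_up = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_low * mse) / (
        f_low * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_up * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_up * msr)
    lower = float(np.clip(lower, -1, icc))
    upper = float(np.clip(upper, icc, 1))
    return float(icc), lower, upper


def two_way_anova(data: pd.DataFrame, value: str = "value",
                  factor_a: str = "A", factor_b: str = "B") -> pd.DataFrame:
    """Balanced two-way ANOVA with interaction; F and p per term.

    Raises if any factor cell is empty or the interaction has < 2
    replicates per cell.
    """
    counts = data.groupby([factor_a, factor_b], observed=True)[value].count()
    la = data[factor_a].nunique()
    lb = data[factor_b].nunique()
    if la < 2 or lb < 2:
        raise ValueError("two-way ANOVA needs >= 2 levels per factor")
    if len(counts) < la * lb:
        present = set(counts.index)
        empties = [(a, b) for a in data[factor_a].unique() for b in data[factor_b].unique()
                   if (a, b) not in present]
        raise ValueError(f"empty cells: {empties}")
    if counts.min() < 2:
        raise ValueError("interaction needs >= 2 replicates per cell")
    model = ols(f"{value} ~ C({factor_a}) * C({factor_b})", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table.index = [factor_a, factor_b, f"{factor_a}:{factor_b}", "residual"]
    return table


def compare_groups(panel: pd.DataFrame, *, value_col: str = "normalized",
                   q: float = 5.0, stringent_alpha: float = 0.01,
                   fdr_procedure: str = "two-stage", control: str = "control",
                   allow_cross_experimental: bool = False,
                   groups: Sequence[tuple[str, str]] | None = None
                   ) -> pd.DataFrame:
    """Per-measurement Welch comparisons of each experimental genotype vs control.

    ``panel`` is a tidy frame with columns specimen_id, measurement, raw,
    normalized, genotype (as from :func:`craniomorph.measure.panel_frame`).
    For measurements without a normalized value (angles, centroid sizes) the
    raw value is compared instead. FDR is applied per experimental group
    across its measurement family; a measurement is flagged ``meaningful``
    when it is an FDR discovery and p < ``stringent_alpha``.
    """
    genotypes = [g for g in panel["genotype"].unique() if g != control]
    if groups is None:
        pairs = [(g, control) for g in genotypes]
    else:
        pairs = list(groups)
    for a, b in pairs:
        if control not in (a, b) and not allow_cross_experimental:
            raise ValueError(
                f"comparison {a!r} vs {b!r} does not involve the control group; "
                "experimental genotypes are not compared to one another unless "
                "allow_cross_experimental=True")
    rows: list[GroupComparison] = []
    for exp, ref in pairs:
        comps: list[GroupComparison] = []
        for meas, block in panel.groupby("measurement", sort=False):
            col = value_col if block[value_col].notna().all() else "raw"
            x = block.loc[block["genotype"] == exp, col].to_numpy(float)
            y = block.loc[block["genotype"] == ref, col].to_numpy(float)
            if len(x) < 2 or len(y) < 2:
                continue
            degenerate = x.var(ddof=1) == 0 and y.var(ddof=1) == 0 and x.mean() == y.mean()
            t, df, p = welch_t(x, y)
            try:
                d = cohens_d(x, y)
            except ValueError:
                d = 0.0
            pc = percent_change(x.mean(), y.mean()) if y.mean() != 0 else np.nan
            comps.append(GroupComparison(
                measurement=meas, group=exp, mean_exp=float(x.mean()),
                sd_exp=float(x.std(ddof=1)), n_exp=len(x), mean_ctrl=float(y.mean()),
                sd_ctrl=float(y.std(ddof=1)), n_ctrl=len(y), percent_change=pc,
                t=t, df=df, p=p, q_discovery=False, cohens_d=d, meaningful=False,
                degenerate=degenerate))
        if comps:
            reject, _ = fdr_adjust([c.p for c in comps], q=q, procedure=fdr_procedure)
            for c, rej in zip(comps, reject):
                c.q_discovery = bool(rej)
                c.meaningful = bool(rej and c.p < stringent_alpha)
        rows.extend(comps)
    return pd.DataFrame([c.__dict__ for c in rows])


def reliability_report(first: pd.DataFrame, second: pd.DataFrame,
                       value_col: str = "raw") -> pd.DataFrame:
    """Intraobserver CV per (specimen, measurement) between two landmarking sessions."""
    key = ["specimen_id", "measurement"]
    merged = first.merge(second, on=key, suffixes=("_1", "_2"))
    out = []
    for _, row in merged.iterrows():
        cv, ok = intraobserver_cv(row[f"{value_col}_1"], row[f"{value_col}_2"])
        out.append({"specimen_id": row["specimen_id"], "measurement": row["measurement"],
                    "cv_percent": cv, "replicable": ok})
    return pd.DataFrame(out)
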