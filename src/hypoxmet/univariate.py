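"""Per-feature univariate statistics: heteroscedastic group contrasts,
BH-FDR adjustment, median-ratio fold changes, hypoxia-duration regressions
and cohort-balance checks.

The group-contrast model is a cell-means linear model with group-specific
residual variances.  For two groups its REML solution coincides with Welch's
unequal-variance t-test with Satterthwaite degrees of freedom, which is what
is computed here (vectorized across features); for more than two groups all
pairwise Welch contrasts plus a Welch omnibus ANOVA F are returned.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import ChangeMatrix, ConcentrationMatrix, ValidationError

log = logging.getLogger("hypoxmet")


@dataclass
class GroupContrastResult:
    feature_id: str
    contrast: str  # "A-B" for pairwise, "omnibus" for the Welch ANOVA F
    estimate: float  # log-scale mean difference (A minus B); NaN for omnibus
    se: float
    t_stat: float  # Welch t, or Welch ANOVA F for the omnibus row
    df: float  # Satterthwaite df (denominator df for omnibus)
    p_value: float
    q_value: float = np.nan
    group_variances: dict = field(default_factory=dict)
    untestable: bool = False


def _welch_arrays(xa: np.ndarray, xb: np.ndarray):
    """Vectorized Welch t over columns of two (n_i, p) arrays with NaNs."""
    na = np.sum(~np.isnan(xa), axis=0)
    nb = np.sum(~np.isnan(xb), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ma, mb = np.nanmean(xa, axis=0), np.nanmean(xb, axis=0)
        va = np.nanvar(xa, axis=0, ddof=1)
        vb = np.nanvar(xb, axis=0, ddof=1)
        sa, sb = va / na, vb / nb
        se = np.sqrt(sa + sb)
        t = (ma - mb) / se
        df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    bad = (na < 2) | (nb < 2)
    return ma - mb, se, t, df, p, va, vb, bad


def _welch_anova(columns: list):
    """Welch's heteroscedastic one-way ANOVA, vectorized over features.

    ``columns`` is a list of (n_i, p) arrays, one per group.  Returns
    (F, df2, p, bad) with df1 = k - 1.
    """
    k = len(columns)
    ns = np.array([np.sum(~np.isnan(x), axis=0) for x in columns], dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.array([np.nanmean(x, axis=0) for x in columns])
        vars_ = np.array([np.nanvar(x, axis=0, ddof=1) for x in columns])
        w = ns / vars_
        sw = w.sum(axis=0)
        mw = (w * means).sum(axis=0) / sw
        a = (w * (means - mw) ** 2).sum(axis=0) / (k - 1)
        lam = ((1 - w / sw) ** 2 / (ns - 1)).sum(axis=0) * 3.0 / (k**2 - 1)
        F = a / (1 + 2 * (k - 2) / 3.0 * lam)
        df2 = 1.0 / lam
    p = stats.f.sf(F, k - 1, df2)
    bad = (ns < 2).any(axis=0)
    return F, df2, p, bad


def heteroscedastic_contrast(changes: ChangeMatrix, grouping=None, reference: str = "CONTROL") -> list:
    """Per-feature group contrasts on per-animal changes with group-specific variances.

    ``grouping`` maps animal_id to a contrast label (default: the change
    matrix's treatment groups collapsed to treated vs CONTROL).  With two
    labels one Welch contrast per feature is returned (estimate = non-reference
    minus reference); with more, all pairwise contrasts plus an omnibus Welch
    ANOVA row.  Features with fewer than two observations in any group are
    flagged untestable and carry NaN statistics.
    """
    if grouping is None:
        grouping = {a: ("CONTROL" if g == "CONTROL" else "treated") for a, g in changes.groups.items()}
    labels = pd.Series({a: grouping[a] for a in changes.values.index if a in grouping})
    uniq = sorted(labels.unique())
    if len(uniq) < 2:
        raise ValidationError("need at least two groups for a contrast")

    X = changes.values.loc[labels.index]
    feats = list(X.columns)
    arrays = {g: X.loc[labels[labels == g].index].to_numpy(dtype=float) for g in uniq}

    results: list = []

    def pair_order(a, b):
        # non-reference minus reference; otherwise sorted order
        if b == reference:
            return a, b
        if a == reference:
            return b, a
        return a, b

    for a, b in combinations(uniq, 2):
        a, b = pair_order(a, b)
        est, se, t, df, p, va, vb, bad = _welch_arrays(arrays[a], arrays[b])
        for j, f in enumerate(feats):
            results.append(
                GroupContrastResult(
                    feature_id=f,
                    contrast=f"{a}-{b}",
                    estimate=float(est[j]),
                    se=float(se[j]),
                    t_stat=float(t[j]),
                    df=float(df[j]),
                    p_value=float(p[j]) if not bad[j] else np.nan,
                    group_variances={a: float(va[j]), b: float(vb[j])},
                    untestable=bool(bad[j]),
                )
            )
    if len(uniq) > 2:
        F, df2, p, bad = _welch_anova([arrays[g] for g in uniq])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            omni_vars = {g: np.nanvar(arrays[g], axis=0, ddof=1) for g in uniq}
        for j, f in enumerate(feats):
            results.append(
                GroupContrastResult(
                    feature_id=f,
                    contrast="omnibus",
                    estimate=np.nan,
                    se=np.nan,
                    t_stat=float(F[j]),
                    df=float(df2[j]),
                    p_value=float(p[j]) if not bad[j] else np.nan,
                    group_variances={g: float(omni_vars[g][j]) for g in uniq},
                    untestable=bool(bad[j]),
                )
            )
    return results


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def add_q_values(results: list) -> list:
    """Attach BH q-values to a family of contrast results (untestable rows excluded)."""
    testable = [r for r in results if not r.untestable]
    if testable:
        q = bh_adjust([r.p_value for r in testable])
        for r, qi in zip(testable, q):
            r.q_value = float(qi)
    return results


def contrast_frame(results: list) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "feature_id": r.feature_id, "contrast": r.contrast, "estimate": r.estimate,
            "se": r.se, "statistic": r.t_stat, "df": r.df, "p_value": r.p_value,
            "q_value": r.q_value, "untestable": r.untestable,
        }
        for g, v in r.group_variances.items():
            row[f"var_{g}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class FoldChange:
    feature_id: str
    interval: str
    group: str
    median_ratio: float  # median over animals of conc_t2 / conc_t1, original scale
    percent: float  # 100 * median_ratio
    direction_vs_reference: int = 0  # +1 treated change exceeds control change, -1 reverse
    n_animals: int = 0


_ENDPOINTS = {"EA_over_SA": ("SA", "EA"), "ER_over_EA": ("EA", "ER")}


def _per_animal_ratios(cm: ConcentrationMatrix, interval: str, group_sel) -> pd.DataFrame:
    t1, t2 = _ENDPOINTS[interval]
    samples = cm.samples
    sel_animals = samples.loc[samples["group"].isin(set(group_sel)), "animal_id"].unique()
    frames = {}
    for tp in (t1, t2):
        ix = samples.index[(samples["timepoint"] == tp) & samples["animal_id"].isin(sel_animals)]
        sub = cm.values.loc[ix]
        sub.index = samples.loc[ix, "animal_id"]
        frames[tp] = sub
    animals = frames[t1].index.intersection(frames[t2].index)
    denom = frames[t1].loc[animals]
    ratios = frames[t2].loc[animals] / denom.where(denom > 0)
    return ratios


def fold_change(cm: ConcentrationMatrix, interval: str, group_sel) -> list:
    """Median-ratio fold changes on the original concentration scale.

    Per analyte, the median over selected animals of conc(t2)/conc(t1);
    animals with a missing or zero denominator are excluded, and an analyte
    with no usable animal gets a NaN fold change.
    """
    if interval not in _ENDPOINTS:
        raise ValidationError(f"unknown interval {interval!r}")
    ratios = _per_animal_ratios(cm, interval, group_sel)
    if ratios.shape[0] == 0:
        raise ValidationError("no animal has both timepoints observed")
    med = ratios.median(axis=0, skipna=True)
    n = ratios.notna().sum(axis=0)
    gname = "+".join(sorted(set(group_sel)))
    return [
        FoldChange(f, interval, gname, float(med[f]), float(100.0 * med[f]), 0, int(n[f]))
        for f in ratios.columns
    ]


def signed_fold_change(cm: ConcentrationMatrix, interval: str, treated_groups, control_group: str = "CONTROL") -> pd.DataFrame:
    """Treated and control fold changes side by side with a direction flag.

    direction = +1 when the treated median change exceeds the control one
    (the convention used when presenting changes relative to the control
    group), -1 for the reverse, 0 for ties/missing.
    """
    fc_t = {f.feature_id: f for f in fold_change(cm, interval, treated_groups)}
    fc_c = {f.feature_id: f for f in fold_change(cm, interval, [control_group])}
    rows = []
    for fid, ft in fc_t.items():
        fc = fc_c.get(fid)
        ratio_c = fc.median_ratio if fc else np.nan
        if np.isnan(ft.median_ratio) or np.isnan(ratio_c):
            direction = 0
        else:
            direction = int(np.sign(np.log(ft.median_ratio) - np.log(ratio_c)))
        ft.direction_vs_reference = direction
        rows.append({
            "feature_id": fid, "interval": interval,
            "treated_percent": ft.percent, "control_percent": 100.0 * ratio_c,
            "direction": direction, "n_treated": ft.n_animals,
        })
    return pd.DataFrame(rows)


@dataclass
class DurationRegressionResult:
    feature_id: str
    slope: float  # per minute of hypoxia
    intercept: float
    r2: float
    r2_adj: float
    p_value: float
    n: int
    untestable: bool = False


def duration_regression(feature_values, durations, feature_id: str = "") -> DurationRegressionResult:
    """OLS of a feature's (log-scale) value on hypoxia duration in minutes."""
    x = pd.Series(durations, dtype=float)
    y = pd.Series(feature_values, dtype=float)
    common = x.index.intersection(y.index)
    df = pd.DataFrame({"x": x[common], "y": y[common]}).dropna()
    if len(df) < 4:
        raise ValidationError(f"need >= 4 paired observations, got {len(df)}")
    n = len(df)
    if df["x"].nunique() == 1 or df["y"].nunique() == 1:
        return DurationRegressionResult(feature_id, np.nan, np.nan, np.nan, np.nan, np.nan, n, untestable=True)
    fit = stats.linregress(df["x"], df["y"])
    r2 = fit.rvalue**2
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return DurationRegressionResult(feature_id, float(fit.slope), float(fit.intercept), float(r2), float(r2_adj), float(fit.pvalue), n)


def cohort_balance_check(clinical: pd.DataFrame, grouping) -> pd.DataFrame:
    """Design-bias check: per numeric covariate, one-way ANOVA p plus Tukey HSD pairwise adjusted p."""
    groups = pd.Series(grouping)
    labels = sorted(groups.unique())
    if len(labels) < 2:
        raise ValidationError("need at least two groups for the balance check")
    rows = []
    for cov in clinical.columns:
        vals = pd.to_numeric(clinical[cov], errors="coerce")
        by_group = [vals[groups[groups == g].index].dropna().to_numpy() for g in labels]
        if any(len(v) < 2 for v in by_group) or vals.dropna().nunique() <= 1:
            rows.append({"feature_id": cov, "p_value": np.nan, "untestable": True})
            continue
        anova_p = float(stats.f_oneway(*by_group).pvalue)
        tk = stats.tukey_hsd(*by_group)
        row = {"feature_id": cov, "p_value": anova_p, "untestable": False}
        for (i, a), (j, b) in combinations(enumerate(labels), 2):
            row[f"tukey_p[{a}-{b}]"] = float(tk.pvalue[i, j])
        rows.append(row)
    return pd.DataFrame(rows)
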