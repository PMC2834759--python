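"""Detection filtering, feature engineering, imputation and change computation.

All statistics downstream run on log-transformed data; fold changes alone use
the original concentration scale.  The univariate stage runs on unimputed
features; only the multivariate (PLS) stage sees imputed data, with the
curated ratios recomputed from imputed analyte concentrations.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd

from .datamodel import (
    LOG_FUNCS,
    ChangeMatrix,
    ConcentrationMatrix,
    ConfigurationError,
    FeatureDef,
    FeatureMatrix,
    ValidationError,
)

log = logging.getLogger("hypoxmet")


class DetectionReport(NamedTuple):
    matrix: ConcentrationMatrix
    dropped: list


def detection_filter(cm: ConcentrationMatrix, min_fraction: float = 0.15) -> DetectionReport:
    """Drop analytes observed in fewer than ``min_fraction`` of samples (inclusive threshold).

    The sample set is unchanged; the report lists the dropped analyte ids.
    Idempotent: re-filtering the result drops nothing.
    """
    if not 0 < min_fraction <= 1:
        raise ValidationError("min_fraction must be in (0, 1]")
    if cm.n_samples == 0 or cm.n_analytes == 0:
        raise ValidationError("empty concentration matrix")
    observed_frac = cm.values.notna().mean(axis=0)
    keep = observed_frac[observed_frac >= min_fraction].index
    dropped = [a for a in cm.values.columns if a not in set(keep)]
    if dropped:
        log.info("detection filter dropped %d analytes (< %.0f%% observed): %s", len(dropped), 100 * min_fraction, dropped)
    return DetectionReport(cm.subset_analytes(keep), dropped)


# -- curated sums and ratios --------------------------------------------------

BCAA = ("Val", "Leu", "Ile")  # branched-chain amino acids in the panel
_AAA = ("Phe", "Tyr", "Trp")  # aromatic amino acids

_KNOWN_RATIOS = [
    ("Ala/BCAA", ("Ala",), BCAA),
    ("Gly/BCAA", ("Gly",), BCAA),
    ("Fischer", BCAA, _AAA),
    ("Gln/Glu", ("Gln",), ("Glu",)),
    ("Tyr/Phe", ("Tyr",), ("Phe",)),
    ("Cit/Arg", ("Cit",), ("Arg",)),
    ("Cit/Orn", ("Cit",), ("Orn",)),
    ("Orn/Arg", ("Orn",), ("Arg",)),
    ("Putrescine/Orn", ("Putrescine",), ("Orn",)),
    ("Kynurenine/Trp", ("Kynurenine",), ("Trp",)),
    ("Serotonin/Trp", ("Serotonin",), ("Trp",)),
    ("Dopamine/DOPA", ("Dopamine",), ("DOPA",)),
    ("Met-SO/Met", ("Met-SO",), ("Met",)),
    ("Sarcosine/Gly", ("Sarcosine",), ("Gly",)),
    ("Ser/Gly", ("Ser",), ("Gly",)),
    ("SDMA/ADMA", ("SDMA",), ("ADMA",)),
    ("Spermidine/Putrescine", ("Spermidine",), ("Putrescine",)),
    ("Spermine/Spermidine", ("Spermine",), ("Spermidine",)),
    ("C2/C0", ("C2",), ("C0",)),
    ("C2+C3/C0", ("C2", "C3"), ("C0",)),
    ("Suc/Lac", ("Suc",), ("Lac",)),
    ("Fum/Suc", ("Fum",), ("Suc",)),
]

_ESSENTIAL_AA = ("His", "Ile", "Leu", "Lys", "Met", "Phe", "Thr", "Trp", "Val")


def default_known_features(analytes: pd.DataFrame, bcaa: tuple = BCAA) -> list:
    """The 28 curated compound/metabolite sums and ratios of the targeted panel.

    ``analytes`` is the analyte metadata frame (index analyte_id, column
    analyte_class); class-level sums (total amino acids, total acylcarnitines)
    are resolved against it.  The BCAA membership is configurable because
    panels differ in whether leucine and isoleucine are resolved or combined.
    """
    present = set(analytes.index)
    aa = tuple(a for a in analytes.index[analytes["analyte_class"] == "amino_acid"])
    ac = tuple(a for a in analytes.index[analytes["analyte_class"] == "acylcarnitine"])
    defs = []
    sums = [
        ("BCAA", bcaa),
        ("AAA", _AAA),
        ("TotalAA", aa),
        ("EssentialAA", _ESSENTIAL_AA),
        ("Krebs", ("aKG", "Suc", "Fum")),
        ("TotalAC", ac),
    ]
    for fid, members in sums:
        if len(members) >= 2 and set(members) <= present:
            defs.append(FeatureDef(fid, "sum", tuple(members), (), "known"))
    for fid, num, den in _KNOWN_RATIOS:
        num = bcaa if num == BCAA else num
        den = bcaa if den == BCAA else den
        if set(num) | set(den) <= present:
            defs.append(FeatureDef(fid, "ratio", tuple(num), tuple(den), "known"))
    have = {d.feature_id for d in defs}
    if not {"Ala/BCAA", "Gly/BCAA"} <= have:
        raise ConfigurationError("panel lacks the analytes needed for the Ala/BCAA and Gly/BCAA ratios")
    return defs


def build_features(
    cm: ConcentrationMatrix,
    known: list | None = None,
    ratio_classes: set = (),
    max_ratios: int = 5000,
    log_base: str = "e",
) -> FeatureMatrix:
    """Assemble the log-scale feature matrix: analytes + curated sums/ratios + pairwise ratios.

    Pairwise ratios are enumerated over lexicographically sorted analytes of
    ``ratio_classes`` as unordered pairs (A/B only, A < B), truncated
    deterministically at ``max_ratios``.  A ratio is missing if either
    endpoint is missing or the denominator is zero; a sum is missing if any
    member is missing; a zero concentration maps to a missing log value.
    All of which is counted in the attached ``build_report``.
    """
    known = list(known or [])
    logf = LOG_FUNCS[log_base]
    conc = cm.values

    defs: list = [FeatureDef(a, "analyte", (a,), (), "analyte") for a in conc.columns]
    for d in known:
        absent = set(d.members) - set(conc.columns)
        if absent:
            raise ConfigurationError(f"known feature {d.feature_id!r} references absent analytes {sorted(absent)}")
        defs.append(d)

    if ratio_classes:
        taken = {d.feature_id for d in defs}
        in_classes = sorted(cm.analytes.index[cm.analytes["analyte_class"].isin(set(ratio_classes))])
        pair_defs = []
        for i, a in enumerate(in_classes):
            for b in in_classes[i + 1:]:
                if f"{a}/{b}" in taken or f"{b}/{a}" in taken:
                    continue  # already among the curated ratios
                pair_defs.append(FeatureDef(f"{a}/{b}", "ratio", (a,), (b,), "pairwise"))
                if len(pair_defs) >= max_ratios:
                    break
            if len(pair_defs) >= max_ratios:
                break
        defs.extend(pair_defs)

    seen = set()
    for d in defs:
        if d.feature_id in seen:
            raise ConfigurationError(f"duplicate feature id {d.feature_id!r}")
        seen.add(d.feature_id)

    n_zero_log = n_zero_den = 0
    cols = {}
    arr = conc.to_numpy(dtype=float)
    col_ix = {a: i for i, a in enumerate(conc.columns)}
    for d in defs:
        num = arr[:, [col_ix[a] for a in d.numerator]].sum(axis=1)  # NaN-propagating by design
        if d.kind == "ratio":
            den = arr[:, [col_ix[a] for a in d.denominator]].sum(axis=1)
            zero_den = den == 0
            n_zero_den += int(np.sum(zero_den & ~np.isnan(num)))
            with np.errstate(divide="ignore", invalid="ignore"):
                val = np.where(zero_den, np.nan, num / den)
        else:
            val = num
        zero_val = val == 0
        n_zero_log += int(np.sum(zero_val))
        with np.errstate(divide="ignore", invalid="ignore"):
            cols[d.feature_id] = np.where(zero_val, np.nan, logf(val))

    values = pd.DataFrame(cols, index=conc.index)
    empty = values.columns[values.isna().all(axis=0)]
    if len(empty):
        log.warning("dropping %d features with no observed values: %s", len(empty), list(empty[:5]))
        values = values.drop(columns=empty)
        defs = [d for d in defs if d.feature_id not in set(empty)]

    fm = FeatureMatrix(values, {d.feature_id: d for d in defs}, cm.samples.copy(), log_base)
    fm.build_report = {"n_zero_log": n_zero_log, "n_zero_denominator": n_zero_den, "n_features": len(defs)}
    if n_zero_den:
        log.warning("%d ratio cells had zero denominators and were set missing", n_zero_den)
    return fm


def lls_impute(fm: FeatureMatrix, k: int = 6) -> FeatureMatrix:
    """Local-least-squares imputation from the k most correlated features.

    For each feature with missing entries, the other features are ranked by
    absolute Pearson correlation on pairwise-complete samples (computed once,
    on the pre-imputation matrix); the target is regressed on the top k (plus
    intercept) over samples where target and all predictors are observed, and
    missing entries are filled with the prediction.  Features are processed in
    ascending missing-count order; observed values are never altered.  When
    fewer than k+2 complete samples support the regression (or a predictor is
    itself unavailable in the row being filled), the feature's observed mean
    is used instead, with a warning.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    X = fm.values.to_numpy(dtype=float).copy()
    orig_missing = np.isnan(X)
    if not orig_missing.any():
        return fm.subset(fm.values.columns)

    corr = fm.values.corr(min_periods=4).to_numpy()
    np.fill_diagonal(corr, np.nan)
    col_means = np.nanmean(X, axis=0)
    n, p = X.shape

    order = np.lexsort((np.arange(p), orig_missing.sum(axis=0)))
    n_fallback = 0
    for j in order:
        miss_rows = np.flatnonzero(orig_missing[:, j])
        if miss_rows.size == 0:
            continue
        cj = np.abs(corr[:, j])
        ranked = np.lexsort((np.arange(p), -np.where(np.isnan(cj), -np.inf, cj)))
        ranked = [i for i in ranked if not np.isnan(cj[i])][:k]
        filled = False
        if len(ranked) == k:
            support = ~orig_missing[:, j]
            for i in ranked:
                support &= ~orig_missing[:, i]
            if support.sum() >= k + 2:
                A = np.column_stack([np.ones(support.sum()), X[np.ix_(np.flatnonzero(support), ranked)]])
                beta, *_ = np.linalg.lstsq(A, X[support, j], rcond=None)
                pred_X = X[np.ix_(miss_rows, ranked)]  # working matrix: earlier fills usable
                ok = ~np.isnan(pred_X).any(axis=1)
                X[miss_rows[ok], j] = beta[0] + pred_X[ok] @ beta[1:]
                if (~ok).any():
                    X[miss_rows[~ok], j] = col_means[j]
                    n_fallback += int((~ok).sum())
                filled = True
        if not filled:
            X[miss_rows, j] = col_means[j]
            n_fallback += miss_rows.size

    if n_fallback:
        log.warning("lls_impute fell back to the observed mean for %d cells", n_fallback)
    values = pd.DataFrame(X, index=fm.values.index, columns=fm.values.columns)
    return FeatureMatrix(values, dict(fm.features), fm.samples.copy(), fm.log_base)


def impute_concentrations(cm: ConcentrationMatrix, k: int = 6) -> ConcentrationMatrix:
    """LLS-impute analyte concentrations on the log scale; ratios are recomputed downstream."""
    logged = np.log(cm.values.where(cm.values > 0))
    defs = {a: FeatureDef(a, "analyte", (a,), (), "analyte") for a in cm.values.columns}
    fm = FeatureMatrix(logged, defs, cm.samples.copy(), "e")
    imputed = lls_impute(fm, k=k)
    return ConcentrationMatrix(np.exp(imputed.values), cm.samples.copy(), cm.analytes.copy())


_INTERVAL_ENDPOINTS = {"EA_over_SA": ("SA", "EA"), "ER_over_EA": ("EA", "ER")}


def compute_changes(data, interval: str, log_base: str = "e") -> ChangeMatrix:
    """Per-animal log change between the two timepoints of ``interval``.

    Accepts a ConcentrationMatrix (log taken here) or a FeatureMatrix
    (already log scale; rescaled to ``log_base`` if needed).  An entry is
    observed only if both endpoint values are; animals missing an entire
    timepoint are excluded with a warning.
    """
    if interval not in _INTERVAL_ENDPOINTS:
        raise ValidationError(f"unknown interval {interval!r}")
    t1, t2 = _INTERVAL_ENDPOINTS[interval]

    samples = data.samples
    if isinstance(data, ConcentrationMatrix):
        logf = LOG_FUNCS[log_base]
        vals = logf(data.values.where(data.values > 0))
    else:
        scale = {"e": 1.0, "2": np.log(2.0), "10": np.log(10.0)}
        vals = data.values * (scale[data.log_base] / scale[log_base])

    by_tp = {}
    for tp in (t1, t2):
        sel = samples.index[samples["timepoint"] == tp]
        sub = vals.loc[sel]
        sub.index = samples.loc[sel, "animal_id"]
        by_tp[tp] = sub

    animals = by_tp[t1].index.intersection(by_tp[t2].index)
    skipped = by_tp[t1].index.symmetric_difference(by_tp[t2].index)
    if len(skipped):
        log.warning("excluding %d animals missing a %s/%s timepoint: %s", len(skipped), t1, t2, list(skipped[:5]))
    if len(animals) == 0:
        raise ValidationError(f"no animal has both {t1} and {t2} samples")

    changes = by_tp[t2].loc[animals] - by_tp[t1].loc[animals]
    changes.index.name = "animal_id"
    groups = samples.drop_duplicates("animal_id").set_index("animal_id").loc[animals, "group"]
    return ChangeMatrix(changes, interval, groups, log_base)
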