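"""Pipeline orchestration: simulate -> preprocess -> univariate -> duration-model -> heatmap.

Stages communicate through delimited-text files in a run directory, so each
stage is independently re-runnable; a manifest records the seed, the config
hash and the package version.  With a fixed config and seed every stage is
deterministic, hence reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datamodel import ConfigurationError, FeatureDef, FeatureMatrix
from .io import (
    FLOAT_FMT,
    read_concentration_table,
    write_concentration_matrix,
    write_result_table,
)
from .preprocess import (
    build_features,
    compute_changes,
    default_known_features,
    detection_filter,
    impute_concentrations,
)
from .synthetic import TREATED_GROUPS, CohortConfig, generate_cohort, inject_missingness
from .univariate import (
    add_q_values,
    bh_adjust,
    cohort_balance_check,
    contrast_frame,
    duration_regression,
    heteroscedastic_contrast,
    signed_fold_change,
)
from .pls import reduce_and_refit
from .clustering import build_heatmap_layout, cut_columns

log = logging.getLogger("hypoxmet")

DEFAULT_RATIO_CLASSES = ("acylcarnitine", "amino_acid", "biogenic_amine", "energy_metabolism")


@dataclass
class PipelineConfig:
    seed: int = 0
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides
    min_detect: float = 0.15
    impute_k: int = 6
    ratio_classes: tuple = DEFAULT_RATIO_CLASSES
    max_ratios: int = 5000
    alpha: float = 0.01
    duration_response: str = "EA"  # EA level (default) or EA_over_SA change
    pls_folds: int = 10
    pls_n_perm: int = 5000
    pls_vip_threshold: float = 1.0
    pls_A_max: int = 10
    heatmap_k: int = 5
    heatmap_log_base: str = "2"
    heatmap_clip: float = 3.0
    heatmap_sig_q: float = 0.01

    def __post_init__(self):
        if not 0 < self.min_detect <= 1:
            raise ConfigurationError("min_detect must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.duration_response not in ("EA", "EA_over_SA"):
            raise ConfigurationError("duration_response must be 'EA' or 'EA_over_SA'")
        self.ratio_classes = tuple(self.ratio_classes)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ratio_classes"] = list(d["ratio_classes"])
        return d

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    def cohort_config(self) -> CohortConfig:
        kw = dict(self.cohort)
        kw.setdefault("seed", self.seed)
        return CohortConfig(**kw)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


def _dir(rundir) -> Path:
    p = Path(rundir)
    p.mkdir(parents=True, exist_ok=True)
    return p


# -- stages -------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, rundir) -> None:
    rundir = _dir(rundir)
    cc = config.cohort_config()
    cm, truth = generate_cohort(cc)
    cm = inject_missingness(cm, cc)
    write_concentration_matrix(cm, rundir / "concentrations.csv", rundir / "analytes.csv", rundir / "samples.csv")
    truth_doc = {
        "durations": {a: float(d) for a, d in truth.durations.items()},
        "informative_features": {f: float(s) for f, s in truth.informative_features.items()},
        "planted_fc": [
            {"analyte": a, "interval": iv, "group": g, "median_ratio": float(r)}
            for (a, iv, g), r in sorted(truth.planted_fc.items())
        ],
    }
    with open(rundir / "truth.yaml", "w") as fh:
        yaml.safe_dump(truth_doc, fh, sort_keys=True)
    log.info("simulate: wrote %d samples x %d analytes", cm.n_samples, cm.n_analytes)


def _read_cm(rundir):
    return read_concentration_table(rundir / "concentrations.csv", rundir / "analytes.csv", rundir / "samples.csv")


def _write_fm(fm: FeatureMatrix, path: Path, defs_path: Path | None = None) -> None:
    fm.values.to_csv(path, float_format=FLOAT_FMT, index_label="sample_id", na_rep="")
    if defs_path is not None:
        rows = [
            {"feature_id": d.feature_id, "kind": d.kind, "numerator": ";".join(d.numerator),
             "denominator": ";".join(d.denominator), "source": d.source}
            for d in fm.features.values()
        ]
        pd.DataFrame(rows).to_csv(defs_path, index=False)


def _read_fm(rundir, path, defs_path, log_base="e") -> FeatureMatrix:
    from .io import read_sample_meta

    values = pd.read_csv(path, index_col=0)
    values.index = values.index.astype(str)
    defs_df = pd.read_csv(defs_path).fillna("")
    defs = {}
    for _, r in defs_df.iterrows():
        num = tuple(x for x in str(r["numerator"]).split(";") if x)
        den = tuple(x for x in str(r["denominator"]).split(";") if x)
        defs[r["feature_id"]] = FeatureDef(r["feature_id"], r["kind"], num, den, r["source"])
    samples = read_sample_meta(Path(rundir) / "samples.csv").loc[values.index]
    return FeatureMatrix(values, defs, samples, log_base)


def stage_preprocess(config: PipelineConfig, rundir) -> None:
    rundir = _dir(rundir)
    cm = _read_cm(rundir)
    filtered, dropped = detection_filter(cm, config.min_detect)
    (rundir / "detection_dropped.txt").write_text("\n".join(dropped) + ("\n" if dropped else ""))

    known = default_known_features(filtered.analytes)
    # univariate features: analytes + the curated sums/ratios, unimputed
    fm = build_features(filtered, known, ratio_classes=(), log_base="e")
    _write_fm(fm, rundir / "features.csv", rundir / "feature_defs.csv")
    for interval in ("EA_over_SA", "ER_over_EA"):
        ch = compute_changes(fm, interval)
        ch.values.to_csv(rundir / f"changes_{interval}.csv", float_format=FLOAT_FMT, index_label="animal_id", na_rep="")

    # multivariate features: imputed analytes, ratios recomputed, pairwise ratios added
    imputed = impute_concentrations(filtered, k=config.impute_k)
    fm_pls = build_features(imputed, known, ratio_classes=config.ratio_classes, max_ratios=config.max_ratios, log_base="e")
    pls_ids = [
        d.feature_id
        for d in fm_pls.features.values()
        if d.source == "pairwise"
        or (d.kind == "analyte" and filtered.analytes.loc[d.feature_id, "analyte_class"] in config.ratio_classes)
        or (d.source == "known" and all(a in filtered.analytes.index and filtered.analytes.loc[a, "analyte_class"] in config.ratio_classes for a in d.members))
    ]
    _write_fm(fm_pls.subset(pls_ids), rundir / "pls_features.csv", rundir / "pls_feature_defs.csv")
    log.info("preprocess: %d univariate features, %d multivariate features (%d analytes dropped)",
             fm.values.shape[1], len(pls_ids), len(dropped))


def _load_changes(rundir, interval, samples) -> "pd.DataFrame":
    df = pd.read_csv(Path(rundir) / f"changes_{interval}.csv", index_col=0)
    df.index = df.index.astype(str)
    return df


def stage_univariate(config: PipelineConfig, rundir) -> None:
    from .datamodel import ChangeMatrix
    from .io import read_sample_meta

    rundir = _dir(rundir)
    samples = read_sample_meta(rundir / "samples.csv")
    groups_by_animal = samples.drop_duplicates("animal_id").set_index("animal_id")["group"]
    cm = _read_cm(rundir)

    families = {
        "hypoxia": ("EA_over_SA", None),  # treated vs control
        "reoxygenation": ("ER_over_EA", None),
        "protocol": ("ER_over_EA", "protocol"),  # between reoxygenation groups
    }
    for family, (interval, mode) in families.items():
        vals = _load_changes(rundir, interval, samples)
        ch = ChangeMatrix(vals, interval, groups_by_animal.loc[vals.index])
        if mode == "protocol":
            treated = [a for a in vals.index if groups_by_animal[a] != "CONTROL"]
            ch = ChangeMatrix(vals.loc[treated], interval, groups_by_animal.loc[treated])
            grouping = groups_by_animal.loc[treated].to_dict()
        else:
            grouping = None
        results = add_q_values(heteroscedastic_contrast(ch, grouping))
        write_result_table(contrast_frame(results), rundir / f"univariate_{family}.csv")
        n_sig = sum(1 for r in results if not r.untestable and r.q_value < config.alpha)
        log.info("univariate[%s]: %d/%d results with q < %g", family, n_sig, len(results), config.alpha)

    for interval in ("EA_over_SA", "ER_over_EA"):
        fc = signed_fold_change(cm, interval, TREATED_GROUPS)
        write_result_table(fc, rundir / f"fold_changes_{interval}.csv")

    # duration regressions on treated animals
    fm = _read_fm(rundir, rundir / "features.csv", rundir / "feature_defs.csv")
    y = _durations(samples)
    X = _duration_response_matrix(config, rundir, fm, samples)
    rows = []
    for f in X.columns:
        try:
            r = duration_regression(X[f], y, feature_id=f)
        except Exception:
            continue
        if not r.untestable:
            rows.append({"feature_id": f, "slope": r.slope, "intercept": r.intercept,
                         "r2": r.r2, "r2_adj": r.r2_adj, "p_value": r.p_value, "n": r.n})
    dr = pd.DataFrame(rows)
    dr["q_value"] = bh_adjust(dr["p_value"].to_numpy())
    write_result_table(dr, rundir / "duration_regressions.csv")

    clinical_cols = [c for c in ("hypoxia_duration",)]
    balance = cohort_balance_check(
        samples.drop_duplicates("animal_id").set_index("animal_id")[clinical_cols],
        groups_by_animal[groups_by_animal != "CONTROL"],
    )
    write_result_table(balance, rundir / "cohort_balance.csv")


def _durations(samples: pd.DataFrame) -> pd.Series:
    per_animal = samples.drop_duplicates("animal_id").set_index("animal_id")
    treated = per_animal[per_animal["group"] != "CONTROL"]
    return treated["hypoxia_duration"].astype(float)


def _duration_response_matrix(config: PipelineConfig, rundir, fm: FeatureMatrix, samples: pd.DataFrame) -> pd.DataFrame:
    """Feature values regressed on duration: EA levels (default) or EA/SA changes, treated animals."""
    treated_animals = samples.loc[samples["group"] != "CONTROL", "animal_id"].unique()
    if config.duration_response == "EA":
        ea = samples.index[(samples["timepoint"] == "EA") & samples["animal_id"].isin(treated_animals)]
        X = fm.values.loc[ea].copy()
        X.index = samples.loc[ea, "animal_id"]
        return X
    ch = _load_changes(rundir, "EA_over_SA", samples)
    return ch.loc[[a for a in ch.index if a in set(treated_animals)]]


def stage_duration_model(config: PipelineConfig, rundir) -> None:
    from .io import read_sample_meta

    rundir = _dir(rundir)
    samples = read_sample_meta(rundir / "samples.csv")
    fm = _read_fm(rundir, rundir / "pls_features.csv", rundir / "pls_feature_defs.csv")
    X = _duration_response_matrix(config, rundir, fm, samples)
    y = _durations(samples).loc[X.index]

    report = reduce_and_refit(
        X, y.to_numpy(), vip_threshold=config.pls_vip_threshold, A_max=config.pls_A_max,
        n_folds=config.pls_folds, n_perm=config.pls_n_perm, seed=config.seed,
    )
    doc = {
        "r2": float(report.r2), "r2_adj": float(report.r2_adj), "q2": float(report.q2),
        "rmse_minutes": float(report.rmse), "empirical_p": float(report.empirical_p),
        "n_components": int(report.n_components), "n_selected": len(report.selected_features),
        "full_model": {"r2": float(report.full_r2), "q2": float(report.full_q2),
                       "rmse_minutes": float(report.full_rmse), "n_components": int(report.full_n_components)},
        "selected_features": list(report.selected_features),
    }
    with open(rundir / "pls_report.yaml", "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
    vip_df = report.vip.rename("vip").to_frame()
    if report.vip_stability is not None:
        vip_df = vip_df.join(report.vip_stability, how="left")
    vip_df.index.name = "feature_id"
    vip_df.reset_index().to_csv(rundir / "pls_vip.csv", float_format=FLOAT_FMT, index=False)

    model_red = None  # fitted-vs-actual table from the reduced model
    from .pls import fit_pls1

    model_red = fit_pls1(X[report.selected_features], y.to_numpy(), report.n_components)
    pd.DataFrame({"animal_id": X.index, "actual_minutes": y.to_numpy(), "fitted_minutes": model_red.fitted}).to_csv(
        rundir / "pls_fitted_vs_actual.csv", float_format=FLOAT_FMT, index=False
    )
    log.info("duration-model: R2=%.3f Q2=%.3f RMSE=%.1f min p=%.4g (%d features)",
             report.r2, report.q2, report.rmse, report.empirical_p, len(report.selected_features))


def stage_heatmap(config: PipelineConfig, rundir) -> None:
    from .datamodel import ChangeMatrix
    from .io import read_sample_meta

    rundir = _dir(rundir)
    samples = read_sample_meta(rundir / "samples.csv")
    groups_by_animal = samples.drop_duplicates("animal_id").set_index("animal_id")["group"]
    fm = _read_fm(rundir, rundir / "features.csv", rundir / "feature_defs.csv")

    sig = set()
    for family in ("hypoxia", "reoxygenation"):
        df = pd.read_csv(rundir / f"univariate_{family}.csv")
        sig |= set(df.loc[df["q_value"] < config.heatmap_sig_q, "feature_id"])
    if len(sig) < max(config.heatmap_k, 10):
        hx = pd.read_csv(rundir / "univariate_hypoxia.csv").sort_values("p_value")
        sig |= set(hx["feature_id"].head(40))
        log.warning("heatmap: too few significant features at q<%g; padded with top hypoxia features", config.heatmap_sig_q)
    feats = [f for f in fm.values.columns if f in sig]

    changes = {}
    for interval in ("EA_over_SA", "ER_over_EA"):
        ch = compute_changes(fm.subset(feats), interval, log_base=config.heatmap_log_base)
        changes[interval] = ch
    controls = groups_by_animal.index[groups_by_animal == "CONTROL"]
    layout = build_heatmap_layout(changes, controls, k=config.heatmap_k, seed=config.seed, clip=config.heatmap_clip)

    layout.matrix.to_csv(rundir / "heatmap_matrix.csv", float_format=FLOAT_FMT, index_label="feature_id", na_rep="")
    layout.ordered(clipped=True).to_csv(rundir / "heatmap_display.csv", float_format=FLOAT_FMT, index_label="feature_id", na_rep="")
    layout.row_clusters.rename("cluster").to_frame().assign(order=[layout.row_order.index(f) for f in layout.row_clusters.index]).to_csv(
        rundir / "heatmap_row_clusters.csv", index_label="feature_id"
    )
    col_cut = cut_columns(layout.column_linkage, layout.matrix.columns, 3)
    dendro = {
        "column_order": [str(c) for c in layout.column_order],
        "merges": [[int(a), int(b), float(h), int(n)] for a, b, h, n in layout.column_linkage.tolist()],
        "column_clusters_k3": {str(c): int(v) for c, v in col_cut.items()},
    }
    with open(rundir / "heatmap_columns.json", "w") as fh:
        json.dump(dendro, fh, indent=1, sort_keys=True)
    log.info("heatmap: %d features x %d profiles", layout.matrix.shape[0], layout.matrix.shape[1])


STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "univariate": stage_univariate,
    "duration-model": stage_duration_model,
    "heatmap": stage_heatmap,
}


def run_pipeline(config: PipelineConfig, rundir, stages=None) -> Path:
    """Run the requested stages (default: all) into ``rundir``; returns the run directory."""
    rundir = _dir(rundir)
    for name in stages or list(STAGES):
        try:
            log.info("stage %s ...", name)
            STAGES[name](config, rundir)
        except Exception as exc:  # stage-labelled abort
            raise StageError(name, exc) from exc
    manifest = {
        "package": "hypoxmet",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash,
        "config": config.to_dict(),
    }
    with open(rundir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    _write_summary(config, rundir)
    return rundir


def _write_summary(config: PipelineConfig, rundir: Path) -> None:
    lines = [f"hypoxmet run (seed={config.seed}, config={config.config_hash})", ""]
    for family in ("hypoxia", "reoxygenation", "protocol"):
        path = rundir / f"univariate_{family}.csv"
        if path.exists():
            df = pd.read_csv(path)
            n_sig = int((df["q_value"] < config.alpha).sum())
            lines.append(f"univariate {family}: {n_sig} significant results at q < {config.alpha}")
    dr_path = rundir / "duration_regressions.csv"
    if dr_path.exists():
        dr = pd.read_csv(dr_path).set_index("feature_id")
        for f in ("Ala/BCAA", "Gly/BCAA", "Lac"):
            if f in dr.index:
                lines.append(f"duration regression {f}: R2.adj = {dr.loc[f, 'r2_adj']:.2f}, q = {dr.loc[f, 'q_value']:.2g}")
    pls_path = rundir / "pls_report.yaml"
    if pls_path.exists():
        with open(pls_path) as fh:
            rep = yaml.safe_load(fh)
        lines.append(
            f"reduced PLS model: R2 = {rep['r2']:.2f}, Q2 = {rep['q2']:.2f}, "
            f"RMSE = {rep['rmse_minutes']:.1f} min, p = {rep['empirical_p']:.2g}, "
            f"{rep['n_selected']} features, {rep['n_components']} components"
        )
    (rundir / "summary.txt").write_text("\n".join(lines) + "\n")
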