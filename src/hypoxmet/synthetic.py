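"""Synthetic cohort generator for the asphyxia/resuscitation design.

The generator emulates the statistical structure the analysis pipeline
assumes: 27 treated newborn piglets in three reoxygenation groups (21% O2
n=8; 100% O2 for 15 min n=8; 100% O2 for 60 min n=11) plus 6 sham controls,
each sampled at the start of hypoxia (SA), the end of hypoxia (EA) and the
end of reoxygenation (ER), over a targeted panel of ~213 analytes in nine
compound classes.

All planted effects are multiplicative on concentrations (additive on logs):

* per-animal hypoxia duration d ~ Normal(69, 24) minutes truncated at 0;
* a hypoxic surge multiplies the EA concentration of selected analytes by a
  fold change (Krebs-cycle intermediates and lactate get the largest ones);
* duration-linked analytes additionally gain exp(slope * d) at EA, so
  derived ratios such as Ala/BCAA correlate with the duration of hypoxia;
* reoxygenation reverses a group- and analyte-specific fraction rho of the
  log-scale excursion at ER (rho=1: full return to baseline; rho=0: none),
  so treatment-dependent recovery of the Krebs intermediates is expressible;
* controls drift only by log-normal noise at every timepoint.

The planted parameters are returned as a SyntheticTruth for recovery tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import ConcentrationMatrix, ConfigurationError, GROUPS

TREATED_GROUPS = ("G21", "G100_15", "G100_60")

# -- panel definition ---------------------------------------------------------

_AMINO_ACIDS = [
    "Ala", "Arg", "Asn", "Asp", "Cit", "Gln", "Glu", "Gly", "His", "Ile", "Leu",
    "Lys", "Met", "Orn", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
]
_BIOGENIC_AMINES = [
    "Taurine", "Putrescine", "Spermidine", "Spermine", "Serotonin", "Kynurenine",
    "ADMA", "SDMA", "alpha-AAA", "Carnosine", "Creatinine", "Histamine", "Met-SO",
    "Nitro-Tyr", "OH-Pro", "PEA", "Sarcosine", "DOPA", "Dopamine",
]
_ENERGY = ["Lac", "aKG", "Suc", "Fum"]
_BILE_ACIDS = [
    "CA", "CDCA", "DCA", "GCA", "GCDCA", "GDCA", "GLCA", "GUDCA", "LCA", "TCA",
    "TCDCA", "TDCA", "TLCA", "TUDCA", "UDCA", "HDCA",
]
_OXYSTEROLS = ["24S-OHC", "25-OHC", "27-OHC", "4b-OHC", "7a-OHC", "7b-OHC", "7-KC"]


def _acylcarnitines(n):
    chains = [0, 2, 3, 4, 5, 6, 8, 10, 12, 14, 16, 18]
    names = []
    for suffix in ("", ":1", "-OH", "-DC"):
        names += [f"C{c}{suffix}" for c in chains]
    return names[:n]


def _patterned(prefix, n):
    return [f"{prefix}{i + 1:02d}" for i in range(n)]


DEFAULT_PANEL_SIZES = {
    "acylcarnitine": 40,
    "amino_acid": 21,
    "biogenic_amine": 19,
    "sphingomyelin": 15,
    "glycerophospholipid": 90,
    "hexose": 1,
    "bile_acid": 16,
    "oxysterol": 7,
    "energy_metabolism": 4,
}  # totals 213 analytes

_CLASS_LOG_MEAN = {
    # natural log of a typical plasma concentration in uM, per class
    "acylcarnitine": np.log(2.0),
    "amino_acid": np.log(150.0),
    "biogenic_amine": np.log(5.0),
    "sphingomyelin": np.log(50.0),
    "glycerophospholipid": np.log(30.0),
    "hexose": np.log(4000.0),
    "bile_acid": np.log(1.0),
    "oxysterol": np.log(0.1),
    "energy_metabolism": np.log(300.0),
}


def _panel_names(cls: str, n: int) -> list:
    named = {
        "amino_acid": _AMINO_ACIDS,
        "biogenic_amine": _BIOGENIC_AMINES,
        "energy_metabolism": _ENERGY,
        "bile_acid": _BILE_ACIDS,
        "oxysterol": _OXYSTEROLS,
        "acylcarnitine": _acylcarnitines(48),
        "hexose": ["H1"],
        "sphingomyelin": _patterned("SM", 48),
        "glycerophospholipid": _patterned("PC", 120),
    }[cls]
    if n <= len(named):
        return list(named[:n])
    return list(named) + _patterned(cls[:2].upper() + "x", n - len(named))


def default_surge_fc() -> dict:
    """Median EA/SA fold changes planted during hypoxia.

    Krebs-cycle intermediates and lactate carry the headline surges
    (median ratios 8.5, 2.66, 80 and 5.87 for lactate, alpha-ketoglutarate,
    succinate and fumarate, i.e. 850/266/8000/587 in percent); a realistic
    scatter of amino acids, acylcarnitines and biogenic amines gets moderate
    increases or decreases so ~40-50 analytes respond to hypoxia.
    """
    fc = {"Lac": 8.5, "aKG": 2.66, "Suc": 80.0, "Fum": 5.87}
    fc.update({"Ala": 2.5, "Gly": 1.8, "Glu": 1.6, "Asp": 1.7, "Orn": 1.4, "Lys": 1.35,
               "Phe": 1.3, "Tyr": 1.3, "Met": 1.25, "Pro": 1.3, "Thr": 1.25,
               "Val": 0.85, "Leu": 0.85, "Ile": 0.85})
    for name, f in zip(_acylcarnitines(48), (2.2, 1.9, 1.7, 1.6, 1.5, 1.5, 1.4, 1.4, 1.35, 1.3, 0.75, 0.7)):
        fc[name] = f
    fc.update({"Taurine": 1.6, "Putrescine": 1.5, "Creatinine": 1.4, "Histamine": 1.35,
               "Serotonin": 0.7, "Kynurenine": 0.75, "Sarcosine": 1.3, "Spermidine": 1.25})
    fc["H1"] = 1.4
    return fc


def default_duration_effect() -> dict:
    """Per-minute log-scale slopes planted on EA concentrations.

    Calibrated so the Ala/BCAA and Gly/BCAA ratios reach adjusted R^2 of
    roughly 0.6 and 0.45 against duration under the default noise levels.
    """
    return {"Ala": 0.021, "Gly": 0.016}


def default_recovery_rate() -> dict:
    """Fraction of the log-scale hypoxic excursion reversed at ER, per (analyte, group).

    Lactate declines similarly in all groups; the Krebs intermediates recover
    fastest under 21% reoxygenation and slowest under prolonged 100% oxygen.
    A plain analyte key applies to every treated group.
    """
    rho = {"Lac": 0.85}
    for a in ("Suc", "Fum", "aKG"):
        rho[(a, "G21")] = 0.90
        rho[(a, "G100_15")] = 0.60
        rho[(a, "G100_60")] = 0.35
    return rho


@dataclass
class CohortConfig:
    """Planted parameters of the synthetic cohort; defaults are the study conditions."""

    n_per_group: dict = field(default_factory=lambda: {"G21": 8, "G100_15": 8, "G100_60": 11, "CONTROL": 6})
    n_analytes_per_class: dict = field(default_factory=lambda: dict(DEFAULT_PANEL_SIZES))
    duration_mean: float = 69.0  # minutes
    duration_sd: float = 24.0
    surge_fc: dict = field(default_factory=default_surge_fc)
    recovery_rate: dict = field(default_factory=default_recovery_rate)
    duration_effect: dict = field(default_factory=default_duration_effect)
    noise_sd: float = 0.2  # log_e scale, per timepoint
    baseline_log_sd: float = 0.25  # between-animal spread of each analyte
    missing_rate: float = 0.02
    low_detect_analytes: int = 5
    seed: int = 0

    def __post_init__(self):
        if any(n <= 0 for n in self.n_per_group.values()):
            raise ConfigurationError("group sizes must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if self.duration_sd <= 0:
            raise ConfigurationError("duration_sd must be positive")
        if self.noise_sd < 0 or self.baseline_log_sd < 0:
            raise ConfigurationError("noise levels must be nonnegative")
        unknown = set(self.n_per_group) - set(GROUPS)
        if unknown:
            raise ConfigurationError(f"unknown groups: {sorted(unknown)}")

    def replace(self, **kw) -> "CohortConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort, for parameter-recovery tests."""

    durations: pd.Series  # animal_id -> minutes
    informative_features: dict  # feature_id -> planted per-minute slope (log_e)
    planted_fc: dict  # (analyte_id, interval, group) -> true median concentration ratio


def _rho_for(config: CohortConfig, analyte: str, group: str) -> float:
    if (analyte, group) in config.recovery_rate:
        return config.recovery_rate[(analyte, group)]
    return config.recovery_rate.get(analyte, 1.0)


def generate_cohort(config: CohortConfig | None = None) -> tuple:
    """Generate one cohort; returns (ConcentrationMatrix, SyntheticTruth).

    Fully reproducible from ``config.seed``.  One SA/EA/ER sample per animal;
    no missingness is introduced here (see :func:`inject_missingness`).
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)

    # animals and durations
    animal_ids, groups = [], []
    for g in GROUPS:
        for i in range(config.n_per_group.get(g, 0)):
            animal_ids.append(f"{g}_{i + 1:02d}")
            groups.append(g)
    groups = pd.Series(groups, index=animal_ids, name="group")

    durations = {}
    for a in animal_ids:
        if groups[a] == "CONTROL":
            durations[a] = 0.0
        else:
            d = rng.normal(config.duration_mean, config.duration_sd)
            while d <= 0:  # truncate at 0: durations are physical
                d = rng.normal(config.duration_mean, config.duration_sd)
            durations[a] = float(d)
    durations = pd.Series(durations, name="hypoxia_duration")

    # analyte panel
    analyte_ids, classes = [], []
    for cls in DEFAULT_PANEL_SIZES:
        n = config.n_analytes_per_class.get(cls, 0)
        for name in _panel_names(cls, n):
            analyte_ids.append(name)
            classes.append(cls)
    analytes = pd.DataFrame({"analyte_class": classes, "display_name": analyte_ids}, index=pd.Index(analyte_ids, name="analyte_id"))

    p = len(analyte_ids)
    n_animals = len(animal_ids)
    mu = np.array([_CLASS_LOG_MEAN[c] for c in classes]) + rng.normal(0.0, 1.0, size=p)
    baseline = mu + rng.normal(0.0, config.baseline_log_sd, size=(n_animals, p))

    absent = (set(config.duration_effect) | set(config.surge_fc)) - set(analyte_ids)
    if absent:
        import logging

        logging.getLogger("hypoxmet").warning(
            "planted effects reference analytes absent from the panel (ignored): %s", sorted(absent)[:10]
        )
    log_fc = np.array([np.log(config.surge_fc.get(a, 1.0)) for a in analyte_ids])
    slope = np.array([config.duration_effect.get(a, 0.0) for a in analyte_ids])
    treated = (groups != "CONTROL").to_numpy()
    dur = durations[animal_ids].to_numpy()

    # deterministic log-scale excursion at EA, per animal x analyte
    delta = np.where(treated[:, None], log_fc[None, :] + slope[None, :] * dur[:, None], 0.0)
    rho = np.array([[_rho_for(config, a, g) if g != "CONTROL" else 0.0 for a in analyte_ids] for g in groups])

    eps = rng.normal(0.0, config.noise_sd, size=(3, n_animals, p)) if config.noise_sd > 0 else np.zeros((3, n_animals, p))
    log_sa = baseline + eps[0]
    log_ea = baseline + delta + eps[1]
    log_er = baseline + (1.0 - rho) * delta + eps[2]

    rows, sample_ids, meta_rows = [], [], []
    for i, a in enumerate(animal_ids):
        for tp, mat in (("SA", log_sa), ("EA", log_ea), ("ER", log_er)):
            sample_ids.append(f"{a}_{tp}")
            rows.append(np.exp(mat[i]))
            meta_rows.append({"animal_id": a, "group": groups[a], "timepoint": tp, "hypoxia_duration": durations[a]})
    values = pd.DataFrame(np.asarray(rows), index=pd.Index(sample_ids, name="sample_id"), columns=analytes.index)
    samples = pd.DataFrame(meta_rows, index=values.index)

    truth = SyntheticTruth(
        durations=durations,
        informative_features=_informative_features(config),
        planted_fc=_planted_fc(config, analyte_ids),
    )
    return ConcentrationMatrix(values, samples, analytes), truth


def _informative_features(config: CohortConfig) -> dict:
    info = dict(config.duration_effect)
    # duration effects planted on Ala/Gly propagate to the headline ratios
    for a, ratio in (("Ala", "Ala/BCAA"), ("Gly", "Gly/BCAA")):
        if a in config.duration_effect:
            info[ratio] = config.duration_effect[a]
    return info


def _planted_fc(config: CohortConfig, analyte_ids) -> dict:
    """Population median concentration ratios implied by the planted parameters."""
    out = {}
    d_med = config.duration_mean  # truncation at 0 is negligible at 69 +/- 24
    for a in analyte_ids:
        base = config.surge_fc.get(a, 1.0)
        sl = config.duration_effect.get(a, 0.0)
        for g in TREATED_GROUPS:
            delta = np.log(base) + sl * d_med
            out[(a, "EA_over_SA", g)] = float(np.exp(delta))
            out[(a, "ER_over_EA", g)] = float(np.exp(-_rho_for(config, a, g) * delta))
        out[(a, "EA_over_SA", "CONTROL")] = 1.0
        out[(a, "ER_over_EA", "CONTROL")] = 1.0
    return out


def inject_missingness(cm: ConcentrationMatrix, config: CohortConfig) -> ConcentrationMatrix:
    """Apply MCAR missingness plus a set of near-undetectable analytes.

    Cells go missing completely at random at ``missing_rate``;
    ``low_detect_analytes`` uninformative analytes are additionally left
    observed in only ~10% of samples, below the 15% detection threshold, so
    the downstream filter has work to do.  Reproducible from ``config.seed``
    (an independent stream from the cohort draw).
    """
    rng = np.random.default_rng([config.seed, 7919])
    values = cm.values.copy()
    n, p = values.shape

    if config.missing_rate > 0:
        mcar = rng.random((n, p)) < config.missing_rate
        values = values.mask(pd.DataFrame(mcar, index=values.index, columns=values.columns))

    if config.low_detect_analytes > 0:
        informative = set(config.surge_fc) | set(config.duration_effect) | {"Val", "Leu", "Ile"}
        eligible = [a for a in values.columns if a not in informative]
        if len(eligible) < config.low_detect_analytes:
            raise ConfigurationError("not enough uninformative analytes to mark as low-detection")
        chosen = rng.choice(eligible, size=config.low_detect_analytes, replace=False)
        n_obs = int(0.10 * n)
        for a in chosen:
            keep = rng.choice(n, size=n_obs, replace=False)
            col = np.full(n, np.nan)
            col[keep] = values[a].to_numpy()[keep]
            values[a] = col

    return ConcentrationMatrix(values, cm.samples.copy(), cm.analytes.copy())
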