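"""Core data containers for targeted-metabolomics concentration data.

Concentrations live in wide samples x analytes tables (micromolar); missing
values are explicit (NaN in the backing DataFrame).  A literal 0 is a valid,
observed concentration -- only empty/sentinel cells are missing, so the
detection filter can distinguish "not detected in this run" from "quantified
as zero".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ANALYTE_CLASSES = (
    "acylcarnitine",
    "amino_acid",
    "biogenic_amine",
    "sphingomyelin",
    "glycerophospholipid",
    "hexose",
    "bile_acid",
    "oxysterol",
    "energy_metabolism",
)

GROUPS = ("G21", "G100_15", "G100_60", "CONTROL")
TIMEPOINTS = ("SA", "EA", "ER")
INTERVALS = ("EA_over_SA", "ER_over_EA")


class FormatError(ValueError):
    """Malformed input table (duplicate ids, bad header, unparsable cell)."""


class ValidationError(ValueError):
    """Structurally valid input that violates a domain invariant."""


class ConfigurationError(ValueError):
    """Inconsistent or out-of-range configuration."""


@dataclass(frozen=True)
class AnalyteMeta:
    analyte_id: str
    analyte_class: str
    display_name: str = ""

    def __post_init__(self):
        if self.analyte_class not in ANALYTE_CLASSES:
            raise ValidationError(
                f"unknown analyte class {self.analyte_class!r} for {self.analyte_id!r}; "
                f"expected one of {ANALYTE_CLASSES}"
            )
        if not self.display_name:
            object.__setattr__(self, "display_name", self.analyte_id)


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    animal_id: str
    group: str
    timepoint: str
    hypoxia_duration: float

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r} for sample {self.sample_id!r}")
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(f"unknown timepoint {self.timepoint!r} for sample {self.sample_id!r}")
        if self.hypoxia_duration < 0:
            raise ValidationError(f"negative hypoxia duration for sample {self.sample_id!r}")
        if self.group == "CONTROL" and self.hypoxia_duration != 0:
            raise ValidationError(f"CONTROL sample {self.sample_id!r} must have hypoxia_duration 0")


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what}: {dupes}")


@dataclass
class ConcentrationMatrix:
    """Samples x analytes concentrations (uM) with explicit missingness.

    ``values`` is a float DataFrame indexed by sample_id with analyte_id
    columns; NaN encodes missing.  ``samples`` and ``analytes`` are metadata
    frames aligned with the rows/columns of ``values``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame  # index sample_id; columns animal_id, group, timepoint, hypoxia_duration
    analytes: pd.DataFrame  # index analyte_id; columns analyte_class, display_name

    def __post_init__(self):
        _check_unique(self.values.index, "sample_id")
        _check_unique(self.values.columns, "analyte_id")
        if not self.values.index.equals(self.samples.index):
            raise ValidationError("sample metadata does not match matrix rows")
        if not self.values.columns.equals(self.analytes.index):
            raise ValidationError("analyte metadata does not match matrix columns")
        vals = self.values.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValidationError("negative concentrations present")
        bad = set(self.analytes["analyte_class"]) - set(ANALYTE_CLASSES)
        if bad:
            raise ValidationError(f"unknown analyte classes: {sorted(bad)}")
        pair = self.samples.reset_index()[["animal_id", "timepoint"]]
        if pair.duplicated().any():
            raise ValidationError("duplicate (animal_id, timepoint) pairs in sample metadata")
        ngroup = self.samples.groupby("animal_id")["group"].nunique()
        if (ngroup > 1).any():
            raise ValidationError("an animal is assigned to more than one group")

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean frame, True where the concentration is missing."""
        return self.values.isna()

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_analytes(self) -> int:
        return self.values.shape[1]

    def subset_analytes(self, analyte_ids) -> "ConcentrationMatrix":
        ids = list(analyte_ids)
        return ConcentrationMatrix(self.values[ids].copy(), self.samples.copy(), self.analytes.loc[ids].copy())

    def subset_samples(self, sample_ids) -> "ConcentrationMatrix":
        ids = list(sample_ids)
        return ConcentrationMatrix(self.values.loc[ids].copy(), self.samples.loc[ids].copy(), self.analytes.copy())

    def copy(self) -> "ConcentrationMatrix":
        return ConcentrationMatrix(self.values.copy(), self.samples.copy(), self.analytes.copy())


@dataclass(frozen=True)
class FeatureDef:
    """Definition of a statistical feature: a raw analyte, a sum, or a ratio.

    ``numerator``/``denominator`` are tuples of analyte ids; a ratio divides
    the sum of numerator concentrations by the sum of denominator
    concentrations, so Ala/BCAA is numerator=(Ala,), denominator=(Val, Leu,
    Ile).  ``source`` records whether the feature is a raw analyte, one of the
    curated panel sums/ratios, or an automatically enumerated pairwise ratio.
    """

    feature_id: str
    kind: str  # analyte | sum | ratio
    numerator: tuple
    denominator: tuple = ()
    source: str = "known"  # analyte | known | pairwise

    def __post_init__(self):
        if self.kind not in ("analyte", "sum", "ratio"):
            raise ValidationError(f"bad feature kind {self.kind!r}")
        if self.kind == "ratio" and (not self.numerator or not self.denominator):
            raise ValidationError(f"ratio {self.feature_id!r} needs numerator and denominator")
        if self.kind == "sum" and (len(self.numerator) < 2 or self.denominator):
            raise ValidationError(f"sum {self.feature_id!r} needs >=2 members and no denominator")
        if self.kind == "analyte" and (len(self.numerator) != 1 or self.denominator):
            raise ValidationError(f"analyte feature {self.feature_id!r} must wrap exactly one analyte")

    @property
    def members(self) -> tuple:
        return tuple(self.numerator) + tuple(self.denominator)


@dataclass
class FeatureMatrix:
    """Samples x features on the log scale, with missingness mask."""

    values: pd.DataFrame  # samples x feature_id, log scale, NaN missing
    features: dict  # feature_id -> FeatureDef
    samples: pd.DataFrame
    log_base: str = "e"  # e | 2 | 10

    def __post_init__(self):
        if self.log_base not in ("e", "2", "10"):
            raise ValidationError(f"log_base must be 'e', '2' or '10', got {self.log_base!r}")
        missing_defs = [c for c in self.values.columns if c not in self.features]
        if missing_defs:
            raise ValidationError(f"features without definitions: {missing_defs[:5]}")
        all_missing = self.values.columns[self.values.isna().all(axis=0)]
        if len(all_missing):
            raise ValidationError(f"features with zero observed values: {list(all_missing[:5])}")

    @property
    def mask(self) -> pd.DataFrame:
        return self.values.isna()

    def subset(self, feature_ids) -> "FeatureMatrix":
        ids = list(feature_ids)
        return FeatureMatrix(
            self.values[ids].copy(),
            {f: self.features[f] for f in ids},
            self.samples.copy(),
            self.log_base,
        )


@dataclass
class ChangeMatrix:
    """Per-animal log-scale changes between two timepoints (animals x features)."""

    values: pd.DataFrame  # index animal_id, columns feature_id; NaN if either endpoint missing
    interval: str  # EA_over_SA | ER_over_EA
    groups: pd.Series  # animal_id -> group
    log_base: str = "e"

    def __post_init__(self):
        if self.interval not in INTERVALS:
            raise ValidationError(f"interval must be one of {INTERVALS}, got {self.interval!r}")
        if not self.values.index.equals(self.groups.index):
            raise ValidationError("groups index does not match change-matrix rows")


LOG_FUNCS = {"e": np.log, "2": np.log2, "10": np.log10}
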