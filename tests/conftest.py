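import numpy as np
import pandas as pd
import pytest

from hypoxmet.datamodel import ConcentrationMatrix
from hypoxmet.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (33 animals x 3 timepoints, 213 analytes), no missingness."""
    return generate_cohort(CohortConfig(seed=42))


@pytest.fixture
def tiny_cm():
    """3 samples x 2 analytes with one missing cell."""
    values = pd.DataFrame(
        {"Ala": [1.0, 2.0, 4.0], "Gly": [0.5, np.nan, 2.0]},
        index=pd.Index(["a_SA", "a_EA", "a_ER"], name="sample_id"),
    )
    samples = pd.DataFrame(
        {
            "animal_id": ["a", "a", "a"],
            "group": ["G21", "G21", "G21"],
            "timepoint": ["SA", "EA", "ER"],
            "hypoxia_duration": [60.0, 60.0, 60.0],
        },
        index=values.index,
    )
    analytes = pd.DataFrame(
        {"analyte_class": ["amino_acid", "amino_acid"], "display_name": ["Ala", "Gly"]},
        index=pd.Index(["Ala", "Gly"], name="analyte_id"),
    )
    return ConcentrationMatrix(values, samples, analytes)


def random_cm(rng, n_animals=5, n_analytes=8):
    """Random valid ConcentrationMatrix across 3 timepoints."""
    animals = [f"G21_{i:02d}" for i in range(n_animals)]
    rows, meta = [], []
    for a in animals:
        for tp in ("SA", "EA", "ER"):
            rows.append(rng.lognormal(1.0, 0.5, size=n_analytes))
            meta.append({"animal_id": a, "group": "G21", "timepoint": tp, "hypoxia_duration": 50.0})
    analyte_ids = [f"M{j:02d}" for j in range(n_analytes)]
    values = pd.DataFrame(rows, index=pd.Index([f"{m['animal_id']}_{m['timepoint']}" for m in meta], name="sample_id"), columns=analyte_ids)
    samples = pd.DataFrame(meta, index=values.index)
    analytes = pd.DataFrame({"analyte_class": ["amino_acid"] * n_analytes, "display_name": analyte_ids}, index=pd.Index(analyte_ids, name="analyte_id"))
    return ConcentrationMatrix(values, samples, analytes)
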