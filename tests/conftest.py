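import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mcri.instruments import SCORE_COLUMNS, CohortTable, ItemCatalog
from mcri.synthetic import SyntheticConfig, generate_cohort

settings.register_profile("ci", derandomize=True, database=None, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def catalog() -> ItemCatalog:
    return ItemCatalog.default()


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition cohort (193 patients) shared across tests."""
    return generate_cohort(SyntheticConfig(), seed=11)


@pytest.fixture(scope="session")
def derived(default_cohort):
    from mcri.pipeline import derive_index

    table, _ = default_cohort
    return derive_index(table, seed=11)


def make_cohort_frame(records: list[dict], catalog: ItemCatalog) -> pd.DataFrame:
    """Build a full-schema cohort frame from sparse record dicts.

    Unspecified items default to mid-range responses; scores are filled
    consistently so the frame passes validation.
    """
    rows = []
    for rec in records:
        row = {}
        for it in catalog.items:
            row[it.item_id] = rec.get(it.item_id, (it.min + it.max) // 2)
        odi = np.array(
            [row[i.item_id] for i in catalog.items if i.instrument == "ODI"], float
        )
        eq = np.array(
            [row[i.item_id] for i in catalog.items if i.instrument == "EQ5D"], float
        )
        hads = np.array(
            [row[i.item_id] for i in catalog.items if i.instrument == "HADS"], float
        )
        answered = ~np.isnan(odi)
        defaults = {
            "NPRS": 5,
            "ODI_pct": (
                float(np.nansum(odi) / (5 * answered.sum()) * 100)
                if answered.any()
                else np.nan
            ),
            "EQ5D_index": 0.3,
            "HADS_total": float(hads.sum()) if not np.isnan(hads).any() else np.nan,
            "Surface_Low": 10.0,
            "Surface_Medium": 5.0,
            "Surface_Intense": 2.0,
            "Surface_VeryIntense": 1.0,
            "PGIC": np.nan,
        }
        row.update(defaults)
        row.update(rec)
        rows.append(row)
    cols = ["patient_id", "visit", *catalog.item_ids, *SCORE_COLUMNS]
    return pd.DataFrame(rows)[cols]


@pytest.fixture()
def tiny_cohort(catalog) -> CohortTable:
    frame = make_cohort_frame(
        [
            {"patient_id": "P1", "visit": "M0"},
            {"patient_id": "P1", "visit": "M3", "PGIC": 6},
            {"patient_id": "P2", "visit": "M0", "ODI_Sitting": 4},
            {"patient_id": "P2", "visit": "M3", "PGIC": 3},
        ],
        catalog,
    )
    return CohortTable(frame, catalog)
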