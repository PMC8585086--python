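"""Data model and CSV I/O for the questionnaire instruments.

The item bank pools three patient-reported instruments — EQ-5D-5L (5 items,
levels 1-5), the Oswestry Disability Index (10 items, 0-5) and the Hospital
Anxiety and Depression Scale (14 items, 0-3) — into a single 29-item
catalog.  Reverse-keyed HADS items are assumed re-coded at data entry so
that a higher response always means a worse symptom state.

A cohort is a longitudinal wide table: one row per (patient, visit), with
the 29 item responses, the instrument-level scores (NPRS, EQ-5D index, ODI
percentage, HADS total), the four pain-map surfaces and the patient global
impression of change (PGIC) at follow-up visits.  Missing cells are allowed
everywhere and are never imputed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VISITS",
    "FOLLOWUP_VISITS",
    "SCORE_COLUMNS",
    "SURFACE_COLUMNS",
    "CLINICAL_REDUNDANCY_REMOVALS",
    "CatalogItem",
    "ItemCatalog",
    "ItemSubset",
    "CohortTable",
    "CohortValidationError",
    "load_cohort",
    "write_cohort",
    "apply_clinical_reduction",
    "pool_across_visits",
    "odi_percentage",
    "hads_total",
]

#: Visit labels, in chronological order: baseline then 3/6/9/12-month follow-up.
VISITS: tuple[str, ...] = ("M0", "M3", "M6", "M9", "M12")
FOLLOWUP_VISITS: tuple[str, ...] = VISITS[1:]

SURFACE_COLUMNS: tuple[str, ...] = (
    "Surface_Low",
    "Surface_Medium",
    "Surface_Intense",
    "Surface_VeryIntense",
)

#: Non-item columns of the cohort CSV, besides patient_id and visit.
SCORE_COLUMNS: tuple[str, ...] = (
    "NPRS",
    "EQ5D_index",
    "ODI_pct",
    "HADS_total",
    *SURFACE_COLUMNS,
    "PGIC",
)

#: Items dropped before any factor analysis because they duplicate constructs
#: measured elsewhere in the battery (the EQ-5D anxiety/depression and
#: pain/discomfort items overlap HADS and NPRS; the first ODI item is itself
#: a pain-intensity rating).
CLINICAL_REDUNDANCY_REMOVALS: tuple[str, ...] = (
    "EQ5D_AnxietyDepression",
    "EQ5D_PainDiscomfort",
    "ODI_PainIntensity",
)


class CohortValidationError(ValueError):
    """Raised when a cohort table violates the schema or response ranges."""


@dataclass(frozen=True)
class CatalogItem:
    item_id: str
    instrument: str
    position: int
    min: int
    max: int
    subscale: str | None
    label: str


@dataclass(frozen=True)
class ItemCatalog:
    """The ordered bank of questionnaire items with response ranges."""

    items: tuple[CatalogItem, ...]

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate item ids in catalog")

    @classmethod
    def default(cls) -> "ItemCatalog":
        """Load the packaged 29-item catalog."""
        raw = json.loads(
            resources.files("mcri.data").joinpath("item_catalog.json").read_text()
        )
        return cls(tuple(CatalogItem(**entry) for entry in raw["items"]))

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    def __len__(self) -> int:
        return len(self.items)

    def __getitem__(self, item_id: str) -> CatalogItem:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def by_label(self, label: str) -> CatalogItem:
        """Resolve an item from its printed row label (e.g. 'Sitting')."""
        hits = [it for it in self.items if it.label == label]
        if len(hits) != 1:
            raise KeyError(f"label {label!r} matches {len(hits)} items")
        return hits[0]


@dataclass(frozen=True)
class ItemSubset:
    """An ordered retained-item list with a provenance tag per catalog item.

    Tags are ``retained``, ``clinical-redundancy`` or ``low-loading``.
    """

    item_ids: tuple[str, ...]
    provenance: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.item_ids)

    def removed(self, tag: str | None = None) -> tuple[str, ...]:
        return tuple(
            i
            for i, t in self.provenance.items()
            if t != "retained" and (tag is None or t == tag)
        )


@dataclass
class CohortTable:
    """A validated longitudinal cohort: one row per (patient, visit)."""

    data: pd.DataFrame
    catalog: ItemCatalog

    def __post_init__(self) -> None:
        _validate(self.data, self.catalog)

    @property
    def n_records(self) -> int:
        return len(self.data)

    def visit(self, label: str) -> pd.DataFrame:
        return self.data[self.data["visit"] == label]

    def completers_per_visit(self) -> dict[str, int]:
        return {v: int((self.data["visit"] == v).sum()) for v in VISITS}

    def equals(self, other: "CohortTable") -> bool:
        a = self.data.reset_index(drop=True)
        b = other.data.reset_index(drop=True)
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for c in a.columns:
            if a[c].dtype == object:
                if not a[c].fillna("").equals(b[c].fillna("")):
                    return False
            else:
                x, y = a[c].to_numpy(float), b[c].to_numpy(float)
                if not np.allclose(x, y, equal_nan=True):
                    return False
        return True


def _columns(catalog: ItemCatalog) -> list[str]:
    return ["patient_id", "visit", *catalog.item_ids, *SCORE_COLUMNS]


def odi_percentage(responses: pd.Series | dict, catalog: ItemCatalog) -> float:
    """Prorated ODI score: sum of answered items / (5 x answered) x 100."""
    ids = [it.item_id for it in catalog.items if it.instrument == "ODI"]
    vals = np.array([responses[i] for i in ids], dtype=float)
    answered = ~np.isnan(vals)
    if not answered.any():
        return float("nan")
    return float(vals[answered].sum() / (5.0 * answered.sum()) * 100.0)


def hads_total(responses: pd.Series | dict, catalog: ItemCatalog) -> float:
    ids = [it.item_id for it in catalog.items if it.instrument == "HADS"]
    vals = np.array([responses[i] for i in ids], dtype=float)
    if np.isnan(vals).any():
        return float("nan")
    return float(vals.sum())


def _validate(df: pd.DataFrame, catalog: ItemCatalog) -> None:
    expected = _columns(catalog)
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        raise CohortValidationError(f"unknown columns: {unknown}")
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing columns: {missing}")

    bad_visits = sorted(set(df["visit"]) - set(VISITS))
    if bad_visits:
        raise CohortValidationError(f"unknown visit labels: {bad_visits}")
    dup = df.duplicated(subset=["patient_id", "visit"])
    if dup.any():
        pairs = df.loc[dup, ["patient_id", "visit"]].values.tolist()
        raise CohortValidationError(f"duplicate (patient, visit) pairs: {pairs}")

    def _coords(mask: pd.Series, col: str) -> str:
        rows = df.loc[mask, ["patient_id", "visit"]].head(5).values.tolist()
        return f"column {col}, (patient, visit) = {rows}"

    for it in catalog.items:
        v = df[it.item_id]
        ok = v.isna() | ((v >= it.min) & (v <= it.max) & (v == np.floor(v)))
        if not ok.all():
            raise CohortValidationError(
                f"response out of range {it.min}-{it.max}: " + _coords(~ok, it.item_id)
            )
    v = df["NPRS"]
    ok = v.isna() | ((v >= 0) & (v <= 10) & (v == np.floor(v)))
    if not ok.all():
        raise CohortValidationError("NPRS out of range 0-10: " + _coords(~ok, "NPRS"))
    for col in SURFACE_COLUMNS:
        v = df[col]
        ok = v.isna() | (v >= 0)
        if not ok.all():
            raise CohortValidationError(f"negative surface: " + _coords(~ok, col))
    v = df["PGIC"]
    ok = v.isna() | ((v >= 1) & (v <= 7) & (v == np.floor(v)))
    if not ok.all():
        raise CohortValidationError("PGIC out of range 1-7: " + _coords(~ok, "PGIC"))
    at_baseline = v.notna() & (df["visit"] == "M0")
    if at_baseline.any():
        raise CohortValidationError(
            "PGIC recorded at baseline: " + _coords(at_baseline, "PGIC")
        )

    # ODI percentage must agree with its items (prorated) when both present.
    odi_ids = [it.item_id for it in catalog.items if it.instrument == "ODI"]
    items = df[odi_ids].to_numpy(float)
    answered = ~np.isnan(items)
    with np.errstate(invalid="ignore"):
        prorated = np.nansum(items, axis=1) / (5.0 * answered.sum(axis=1)) * 100.0
    have_both = df["ODI_pct"].notna().to_numpy() & answered.any(axis=1)
    mism = have_both & (np.abs(df["ODI_pct"].to_numpy(float) - prorated) > 0.51)
    if mism.any():
        raise CohortValidationError(
            "ODI_pct inconsistent with items: " + _coords(pd.Series(mism, index=df.index), "ODI_pct")
        )


def load_cohort(path: str | Path, catalog: ItemCatalog | None = None) -> CohortTable:
    """Read and validate a cohort CSV (wide format, empty cell = missing)."""
    catalog = catalog or ItemCatalog.default()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"patient_id": str, "visit": str})
    for c in df.columns:
        if c not in ("patient_id", "visit"):
            df[c] = pd.to_numeric(df[c], errors="raise")
    return CohortTable(df, catalog)


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write a cohort CSV; missing values become empty cells."""
    df = table.data.copy()
    out = df.copy()
    for it in table.catalog.items:
        out[it.item_id] = df[it.item_id].map(
            lambda x: "" if pd.isna(x) else str(int(x))
        )
    for col in ("NPRS", "HADS_total", "PGIC"):
        out[col] = df[col].map(lambda x: "" if pd.isna(x) else str(int(x)))
    for col in ("EQ5D_index", "ODI_pct", *SURFACE_COLUMNS):
        out[col] = df[col].map(lambda x: "" if pd.isna(x) else repr(float(x)))
    out.to_csv(path, index=False)


def apply_clinical_reduction(source: ItemCatalog | ItemSubset) -> ItemSubset:
    """Drop the three pre-specified clinically redundant items (29 -> 26).

    Idempotent: applying the reduction to an already reduced subset returns
    an equal subset.
    """
    if isinstance(source, ItemCatalog):
        ids = source.item_ids
        prov = {i: "retained" for i in ids}
    else:
        ids = source.item_ids
        prov = dict(source.provenance)
    retained = tuple(i for i in ids if i not in CLINICAL_REDUNDANCY_REMOVALS)
    for i in CLINICAL_REDUNDANCY_REMOVALS:
        if i in prov:
            prov[i] = "clinical-redundancy"
    return ItemSubset(retained, prov)


def pool_across_visits(table: CohortTable, subset: ItemSubset | Sequence[str]) -> pd.DataFrame:
    """Stack complete (patient, visit) records on a retained-item subset.

    Available-case rule: a record enters the pooled observation matrix only
    if every subset item is answered; nothing is imputed.  Rows are indexed
    by (patient_id, visit); columns follow the subset order.
    """
    ids = list(subset.item_ids if isinstance(subset, ItemSubset) else subset)
    if not ids:
        raise ValueError("empty item subset")
    df = table.data.set_index(["patient_id", "visit"])[ids]
    complete = df.dropna(how="any")
    if complete.empty:
        raise ValueError("no complete records on the requested item subset")
    return complete.astype(float)
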