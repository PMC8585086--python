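"""From a fitted factor model to the composite index (MCRI).

The index combines four symptom-burden constructs — a functional-disability
factor score, a depression/anxiety factor score, the 0-10 pain intensity
rating (NPRS) and the pain-mapping intensity (PMI) — via principal
component analysis of their correlation matrix.  Factor scores are
extracted with the Bartlett weighted-least-squares estimator.  The first
principal component, oriented so that a higher value means better health,
is min-max rescaled to [0, 10] on the derivation sample and frozen: scoring
new records never refits anything.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .factor_models import FactorModel
from .instruments import SURFACE_COLUMNS, CohortTable
from .pmi import compute_pmi

__all__ = [
    "CONSTRUCT_NAMES",
    "CompositeModel",
    "bartlett_scores",
    "scale_0_100",
    "construct_scores",
    "fit_composite",
    "apply_mcri",
    "score_records",
]

CONSTRUCT_NAMES: tuple[str, ...] = (
    "functional_disability",
    "depression_anxiety",
    "NPRS",
    "PMI",
)


def bartlett_scores(z: np.ndarray, model: FactorModel) -> np.ndarray:
    """Bartlett (weighted-least-squares) factor scores.

    For standardized item responses z the estimator is
    ``(L' Psi^-1 L)^-1 L' Psi^-1 z`` with L the pattern matrix and Psi the
    uniquenesses implied by the model.  It is conditionally unbiased for
    the true factor values.  Missing responses are an error: no imputation.
    """
    z = np.atleast_2d(np.asarray(z, float))
    if z.shape[1] != len(model.item_ids):
        raise ValueError("item count mismatch with the factor model")
    if np.isnan(z).any():
        raise ValueError("missing item responses; Bartlett scores need complete records")
    psi = model.uniquenesses
    if (psi <= 0).any():
        raise ValueError("nonpositive uniqueness in the factor model")
    L = model.loadings
    A = L.T @ (L / psi[:, None])
    if np.linalg.cond(A) > 1e12:
        raise ValueError("singular Bartlett system (L' Psi^-1 L)")
    W = np.linalg.solve(A, (L / psi[:, None]).T)
    return z @ W.T


def scale_0_100(scores: np.ndarray, bounds: tuple[float, float]) -> tuple[np.ndarray, int]:
    """Affine min-max map onto [0, 100]; out-of-range values are clipped.

    Returns the scaled scores and the number of clipped values (nonzero
    only when scoring data outside the derivation range).
    """
    lo, hi = bounds
    if not hi > lo:
        raise ValueError("degenerate scaling bounds")
    s = np.asarray(scores, float)
    raw = (s - lo) / (hi - lo) * 100.0
    clipped = int(((raw < 0) | (raw > 100)).sum())
    return np.clip(raw, 0.0, 100.0), clipped


@dataclass
class CompositeModel:
    """The frozen definition of the composite index.

    Holds everything needed to score a new record without refitting: the
    item standardization statistics feeding the Bartlett scores, the
    construct standardization statistics, the oriented unit-norm first-PC
    weights, and the [0, 10] min-max bounds from the derivation sample.
    ``component_loadings`` (weights x sqrt(eigenvalue)) are the
    variable-component correlations conventionally reported for a PCA.
    """

    construct_names: tuple[str, ...]
    construct_means: np.ndarray
    construct_sds: np.ndarray
    weights: np.ndarray
    eigenvalue: float
    explained_share: float
    composite_bounds: tuple[float, float]
    item_means: np.ndarray | None = None
    item_sds: np.ndarray | None = None
    construct_bounds_0_100: dict[str, tuple[float, float]] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    #: minimal important change on the [0, 10] scale (anchor-derived)
    micd: float = 1.05

    def __post_init__(self) -> None:
        self.construct_means = np.asarray(self.construct_means, float)
        self.construct_sds = np.asarray(self.construct_sds, float)
        self.weights = np.asarray(self.weights, float)
        if not np.isclose(np.linalg.norm(self.weights), 1.0, atol=1e-8):
            raise ValueError("first-PC weights must be unit-norm")
        if not (0 < self.eigenvalue <= len(self.construct_names)):
            raise ValueError("eigenvalue outside (0, #constructs]")
        lo, hi = self.composite_bounds
        if not hi > lo:
            raise ValueError("degenerate composite bounds")

    @property
    def component_loadings(self) -> np.ndarray:
        return self.weights * np.sqrt(self.eigenvalue)

    def composite_raw(self, constructs: np.ndarray) -> np.ndarray:
        z = (np.atleast_2d(constructs) - self.construct_means) / self.construct_sds
        return z @ self.weights

    def to_10_scale(self, raw: np.ndarray) -> np.ndarray:
        lo, hi = self.composite_bounds
        return np.clip((np.asarray(raw, float) - lo) / (hi - lo) * 10.0, 0.0, 10.0)

    def to_dict(self) -> dict:
        return {
            "construct_names": list(self.construct_names),
            "construct_means": self.construct_means.tolist(),
            "construct_sds": self.construct_sds.tolist(),
            "weights": self.weights.tolist(),
            "eigenvalue": self.eigenvalue,
            "explained_share": self.explained_share,
            "composite_bounds": list(self.composite_bounds),
            "item_means": None if self.item_means is None else self.item_means.tolist(),
            "item_sds": None if self.item_sds is None else self.item_sds.tolist(),
            "construct_bounds_0_100": {k: list(v) for k, v in self.construct_bounds_0_100.items()},
            "provenance": self.provenance,
            "micd": self.micd,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CompositeModel":
        return cls(
            tuple(d["construct_names"]),
            np.array(d["construct_means"], float),
            np.array(d["construct_sds"], float),
            np.array(d["weights"], float),
            float(d["eigenvalue"]),
            float(d["explained_share"]),
            tuple(d["composite_bounds"]),
            None if d["item_means"] is None else np.array(d["item_means"], float),
            None if d["item_sds"] is None else np.array(d["item_sds"], float),
            {k: tuple(v) for k, v in d["construct_bounds_0_100"].items()},
            dict(d["provenance"]),
            float(d["micd"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "CompositeModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _complete_records(table: CohortTable, factor_model: FactorModel) -> pd.DataFrame:
    cols = list(factor_model.item_ids) + ["NPRS", *SURFACE_COLUMNS]
    df = table.data.set_index(["patient_id", "visit"])[cols]
    return df.dropna(how="any").astype(float)


def construct_scores(
    table: CohortTable,
    factor_model: FactorModel,
    item_means: np.ndarray | None = None,
    item_sds: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Per-record construct scores on the pooled available-case sample.

    Items are z-scored (with the supplied statistics, or statistics
    estimated from this sample) and fed to the Bartlett estimator; NPRS and
    PMI are carried through unchanged.  Returns the construct table indexed
    by (patient, visit) plus the item means and sds actually used.
    """
    df = _complete_records(table, factor_model)
    if df.empty:
        raise ValueError("no complete records for construct scoring")
    items = df[list(factor_model.item_ids)].to_numpy(float)
    if item_means is None:
        item_means = items.mean(axis=0)
        item_sds = items.std(axis=0, ddof=1)
    if (np.asarray(item_sds) <= 0).any():
        raise ValueError("constant item in the derivation sample")
    z = (items - item_means) / item_sds
    fs = bartlett_scores(z, factor_model)
    out = pd.DataFrame(index=df.index)
    labels = list(factor_model.factor_labels)
    for name in CONSTRUCT_NAMES[:2]:
        if name not in labels:
            raise ValueError(f"factor model lacks a factor labelled {name!r}")
        out[name] = fs[:, labels.index(name)]
    out["NPRS"] = df["NPRS"].to_numpy(float)
    out["PMI"] = compute_pmi(df[list(SURFACE_COLUMNS)].to_numpy(float))
    return out, np.asarray(item_means, float), np.asarray(item_sds, float)


def fit_composite(
    constructs: pd.DataFrame,
    item_means: np.ndarray | None = None,
    item_sds: np.ndarray | None = None,
    provenance: dict | None = None,
) -> CompositeModel:
    """Derive the composite definition from pooled construct scores.

    The four constructs are z-scored, their correlation matrix
    eigendecomposed, and the first eigenvector oriented so that a higher
    composite means better health (symptom-burden constructs get negative
    weights).  The [0, 10] scaling is the min-max of the derivation-sample
    composite values.
    """
    X = constructs[list(CONSTRUCT_NAMES)].dropna(how="any").to_numpy(float)
    if X.shape[0] <= X.shape[1]:
        raise ValueError("too few complete rows to derive the composite")
    sds = X.std(axis=0, ddof=1)
    if (sds <= 0).any():
        raise ValueError("a construct has zero variance")
    means = X.mean(axis=0)
    Z = (X - means) / sds
    C = np.corrcoef(Z, rowvar=False)
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    if w[0] - w[1] < 1e-8:
        raise ValueError("unstable first component: top eigenvalues tied")
    vec = V[:, 0]
    if vec.sum() > 0:  # orient: burden constructs weighted negatively
        vec = -vec
    raw = Z @ vec
    bounds_10 = (float(raw.min()), float(raw.max()))
    bounds_100 = {
        name: (float(col.min()), float(col.max()))
        for name, col in zip(CONSTRUCT_NAMES, X.T)
    }
    prov = dict(provenance or {})
    prov.setdefault(
        "derivation_sample_hash",
        hashlib.sha256(np.ascontiguousarray(np.round(X, 10)).tobytes()).hexdigest()[:16],
    )
    prov.setdefault("n_records", int(X.shape[0]))
    return CompositeModel(
        CONSTRUCT_NAMES,
        means,
        sds,
        vec,
        float(w[0]),
        float(w[0] / len(CONSTRUCT_NAMES)),
        bounds_10,
        None if item_means is None else np.asarray(item_means, float),
        None if item_sds is None else np.asarray(item_sds, float),
        bounds_100,
        prov,
    )


def score_records(
    model: CompositeModel,
    factor_model: FactorModel,
    records: pd.DataFrame,
) -> pd.DataFrame:
    """Score a batch of complete records; returns constructs + MCRI.

    Rows must contain the factor model's items, NPRS and the four surface
    columns, all non-missing.  The pipeline is: z-score items with the
    frozen statistics, Bartlett factor scores, z-score constructs with the
    frozen statistics, project on the frozen first-PC weights, map to
    [0, 10] with the frozen bounds.  Deterministic, no refitting.
    """
    if model.item_means is None or model.item_sds is None:
        raise ValueError("composite model carries no item standardization statistics")
    need = list(factor_model.item_ids) + ["NPRS", *SURFACE_COLUMNS]
    missing_cols = [c for c in need if c not in records.columns]
    if missing_cols:
        raise ValueError(f"records lack required fields: {missing_cols}")
    sub = records[need].astype(float)
    bad = sub.isna().any(axis=1)
    if bad.any():
        fields = sub.columns[sub[bad].isna().any(axis=0)].tolist()
        raise ValueError(f"missing inputs in fields {fields} for {int(bad.sum())} record(s)")
    items = sub[list(factor_model.item_ids)].to_numpy(float)
    z = (items - model.item_means) / model.item_sds
    fs = bartlett_scores(z, factor_model)
    labels = list(factor_model.factor_labels)
    constructs = np.column_stack([
        fs[:, labels.index("functional_disability")],
        fs[:, labels.index("depression_anxiety")],
        sub["NPRS"].to_numpy(float),
        compute_pmi(sub[list(SURFACE_COLUMNS)].to_numpy(float)),
    ])
    raw = model.composite_raw(constructs)
    out = pd.DataFrame(constructs, columns=list(CONSTRUCT_NAMES), index=records.index)
    out["MCRI"] = model.to_10_scale(raw)
    return out


def apply_mcri(
    model: CompositeModel,
    factor_model: FactorModel,
    record: pd.Series | Mapping,
) -> float:
    """Score a single patient-visit record; returns the MCRI in [0, 10]."""
    row = pd.DataFrame([pd.Series(record)])
    return float(score_records(model, factor_model, row)["MCRI"].iloc[0])
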