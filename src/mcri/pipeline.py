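"""End-to-end derivation, scoring and evaluation of the composite index.

``derive_index`` reproduces the published construction sequence on any
cohort: clinical item reduction (29 -> 26), pooled exploratory factor
analysis with principal-axis extraction and promax rotation, low-loading
pruning (26 -> 23), a refit on the retained items, Bartlett construct
scores, and the correlation-matrix PCA that defines the index.  The fitted
factor and composite models are frozen artifacts; ``score_cohort`` applies
them to (possibly new) records without refitting, and ``evaluate_scored``
produces the anchor-based classification and correlation reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .composite import (
    CompositeModel,
    construct_scores,
    fit_composite,
    score_records,
)
from .evaluation import (
    INSTRUMENT_ORIENTATION,
    INTERVALS,
    PAPER_CUTOFFS,
    change_table,
    confusion_metrics,
    correlation_report,
    jonckheere_terpstra,
    optimal_cutoff,
)
from .factor_models import (
    FactorModel,
    parallel_analysis,
    principal_axis,
    promax,
    prune_items,
    vss_criterion,
)
from .instruments import (
    SURFACE_COLUMNS,
    VISITS,
    CohortTable,
    ItemSubset,
    apply_clinical_reduction,
    pool_across_visits,
)
from .pmi import compute_pmi
from .psychometrics import kmo

__all__ = ["DerivationResult", "derive_index", "score_cohort", "evaluate_scored"]


def _label_factors(model_items: tuple[str, ...], pattern: np.ndarray, phi: np.ndarray) -> FactorModel:
    """Name factors by instrument composition and order disability first.

    The factor carrying more squared loading on the EQ-5D/ODI items is the
    functional-disability factor; the other is depression/anxiety.
    """
    is_hads = np.array([i.startswith("HAD_") for i in model_items])
    ss_phys = (pattern[~is_hads] ** 2).sum(axis=0)
    ss_hads = (pattern[is_hads] ** 2).sum(axis=0)
    disability = int(np.argmax(ss_phys))
    distress = int(np.argmax(ss_hads))
    if disability == distress:
        raise ValueError("could not tell the two factors apart by instrument content")
    order = [disability, distress]
    labels = ("functional_disability", "depression_anxiety")
    return FactorModel(
        model_items,
        pattern[:, order],
        phi[np.ix_(order, order)],
        labels,
    )


@dataclass
class DerivationResult:
    factor_model: FactorModel
    composite_model: CompositeModel
    constructs: pd.DataFrame
    report: dict


def derive_index(
    table: CohortTable,
    n_factors: int = 2,
    loading_threshold: float = 0.3,
    promax_power: int = 4,
    pa_reps: int = 100,
    seed: int = 0,
) -> DerivationResult:
    """Run the full index-construction sequence on a cohort."""
    subset26 = apply_clinical_reduction(table.catalog)
    pooled26 = pool_across_visits(table, subset26)
    R26 = np.corrcoef(pooled26.to_numpy(), rowvar=False)
    kmo26, _ = kmo(R26)
    ev26 = np.sort(np.linalg.eigvalsh(R26))[::-1]
    pa26 = parallel_analysis(len(pooled26), R26.shape[0], ev26, reps=pa_reps, seed=seed)
    vss1_26, _ = vss_criterion(R26, max_factors=4, complexity=1)
    vss2_26, vss26 = vss_criterion(R26, max_factors=4, complexity=2)

    L26, _ = principal_axis(R26, n_factors)
    pat26, phi26 = promax(L26, power=promax_power)
    first_model = _label_factors(subset26.item_ids, pat26, phi26)

    pruned, refit = prune_items(first_model, threshold=loading_threshold)
    # merge provenance: keep the clinical-redundancy tags
    prov = dict(subset26.provenance)
    prov.update({k: v for k, v in pruned.provenance.items() if v == "low-loading"})
    subset_final = ItemSubset(pruned.item_ids, prov)

    pooled = pool_across_visits(table, subset_final)
    R = np.corrcoef(pooled.to_numpy(), rowvar=False)
    kmo_final, _ = kmo(R)
    ev = np.sort(np.linalg.eigvalsh(R))[::-1]
    pa_final = parallel_analysis(len(pooled), R.shape[0], ev, reps=pa_reps, seed=seed)
    vss1_f, _ = vss_criterion(R, max_factors=4, complexity=1)
    vss2_f, vss_final = vss_criterion(R, max_factors=4, complexity=2)

    L, _ = principal_axis(R, n_factors)
    pat, phi = promax(L, power=promax_power)
    factor_model = _label_factors(subset_final.item_ids, pat, phi)

    constructs, item_means, item_sds = construct_scores(table, factor_model)
    composite = fit_composite(
        constructs,
        item_means,
        item_sds,
        provenance={"package_version": __version__, "n_items": len(factor_model.item_ids)},
    )

    report = {
        "package_version": __version__,
        "item_trail": [len(table.catalog), len(subset26), len(subset_final)],
        "removed_clinical": sorted(subset_final.removed("clinical-redundancy")),
        "removed_low_loading": sorted(subset_final.removed("low-loading")),
        "kmo_first": kmo26,
        "kmo_final": kmo_final,
        "parallel_analysis": {"first": pa26, "final": pa_final},
        "vss": {
            "first": {"curve_c1": vss1_26.tolist(), "curve_c2": vss2_26.tolist(), "argmax": vss26},
            "final": {"curve_c1": vss1_f.tolist(), "curve_c2": vss2_f.tolist(), "argmax": vss_final},
        },
        "pooled_n": {"first": int(len(pooled26)), "final": int(len(pooled))},
        "loadings": {
            iid: [float(x) for x in row]
            for iid, row in zip(factor_model.item_ids, factor_model.loadings)
        },
        "phi12": float(factor_model.phi[0, 1]),
        "pca": {
            "weights": composite.weights.tolist(),
            "component_loadings": composite.component_loadings.tolist(),
            "eigenvalue": composite.eigenvalue,
            "explained_share_pct": 100 * composite.explained_share,
        },
        "refit_required": bool(refit),
    }
    return DerivationResult(factor_model, composite, constructs, report)


def score_cohort(
    table: CohortTable,
    factor_model: FactorModel,
    composite_model: CompositeModel,
) -> pd.DataFrame:
    """Score every record of a cohort; one output row per (patient, visit).

    The MCRI is computed for records complete on the model's inputs; rows
    with missing inputs keep a missing MCRI but retain their per-instrument
    scores, so instrument-level analyses stay available-case.
    """
    df = table.data.copy()
    surf = df[list(SURFACE_COLUMNS)].to_numpy(float)
    pmi_col = np.where(np.isnan(surf).any(axis=1), np.nan, np.nan_to_num(surf) @ np.array([1, 2, 3, 4.0]))
    out = df[["patient_id", "visit", "NPRS", "EQ5D_index", "ODI_pct", "HADS_total", "PGIC"]].copy()
    out["PMI"] = pmi_col

    need = list(factor_model.item_ids) + ["NPRS", *SURFACE_COLUMNS]
    complete = df[need].notna().all(axis=1)
    out["MCRI"] = np.nan
    for name in ("functional_disability", "depression_anxiety"):
        out[name] = np.nan
    if complete.any():
        scored = score_records(composite_model, factor_model, df.loc[complete])
        out.loc[complete, "MCRI"] = scored["MCRI"].to_numpy()
        out.loc[complete, "functional_disability"] = scored["functional_disability"].to_numpy()
        out.loc[complete, "depression_anxiety"] = scored["depression_anxiety"].to_numpy()
    out.attrs["n_skipped"] = int((~complete).sum())
    return out


def evaluate_scored(
    scored: pd.DataFrame,
    cutoff_set: str = "paper",
) -> dict:
    """Anchor-based evaluation of a scored cohort.

    Returns a report with, per interval and instrument, the confusion
    counts, sensitivity/specificity at the requested cutoffs ("paper" for
    the published set, "optimal" for Youden-derived ones), the AUC, the
    trend-test result, and per-visit correlation matrices.
    """
    if "PGIC" not in scored.columns:
        raise ValueError("scored table has no PGIC column; anchor evaluation impossible")
    changes = change_table(scored)
    if changes.empty:
        raise ValueError("no baseline/follow-up pairs to evaluate")
    classification: list[dict] = []
    trend: list[dict] = []
    for interval in INTERVALS:
        sub = changes[changes["interval"] == interval]
        if sub.empty:
            continue
        for name in INSTRUMENT_ORIENTATION:
            if name not in sub.columns:
                continue
            ch = sub[name].to_numpy(float)
            sat = sub["satisfied"].to_numpy()
            ok = ~(np.isnan(ch) | pd.isna(sat))
            if ok.sum() < 2 or len(set(map(bool, sat[ok]))) < 2:
                continue
            if cutoff_set == "paper":
                res = confusion_metrics(ch[ok], sat[ok], PAPER_CUTOFFS[name], name, interval)
            elif cutoff_set == "optimal":
                res = optimal_cutoff(ch[ok], sat[ok], name, interval)
            else:
                raise ValueError(f"unknown cutoff set {cutoff_set!r}")
            classification.append(res.display())
            groups = [
                ch[ok][sub["PGIC"].to_numpy(float)[ok] == c]
                for c in sorted(np.unique(sub["PGIC"].to_numpy(float)[ok]))
            ]
            jt = jonckheere_terpstra([g for g in groups if len(g)])
            trend.append(
                {
                    "instrument": name,
                    "interval": interval,
                    "jt_statistic": jt.statistic,
                    "z": jt.z,
                    "p_value": jt.p_value,
                }
            )
    correlations = {}
    for visit in VISITS:
        sub = scored[scored["visit"] == visit]
        if len(sub) >= 4 and sub["MCRI"].notna().sum() >= 4:
            rho, disp, _ = correlation_report(scored, visit)
            correlations[visit] = {
                "rho": rho.round(3).to_dict(),
                "display": disp.to_dict(),
            }
    return {
        "package_version": __version__,
        "cutoff_set": cutoff_set,
        "classification": classification,
        "trend_tests": trend,
        "correlations": correlations,
    }
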