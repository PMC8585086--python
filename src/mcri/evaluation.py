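"""Anchor-based evaluation of score changes against the PGIC.

Change scores between baseline and each follow-up are oriented so that a
positive value always means improvement (baseline - followup for the
symptom-burden scores ODI, NPRS, HADS and PMI; followup - baseline for the
health-oriented MCRI and EQ-5D index).  The anchor dichotomizes the
patient global impression of change at >= 6 ("satisfactory improvement").
Discrimination is summarized by the Mann-Whitney AUC; responder cutoffs
either replicate the published set or are re-derived by maximizing
sensitivity + specificity (the Youden criterion).  The ordered
PGIC-by-change association is tested with the Jonckheere-Terpstra trend
test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .psychometrics import CorrelationSummary, spearman_ci

__all__ = [
    "PAPER_CUTOFFS",
    "INSTRUMENT_ORIENTATION",
    "INTERVALS",
    "ClassificationResult",
    "JTResult",
    "dichotomize_pgic",
    "change_table",
    "confusion_metrics",
    "roc_auc",
    "optimal_cutoff",
    "jonckheere_terpstra",
    "correlation_report",
]

#: Published responder cutoffs on the improvement-oriented change scale.
PAPER_CUTOFFS: dict[str, float] = {
    "MCRI": 1.05,
    "ODI": 6.7,
    "EQ5D": 0.13,
    "NPRS": 2.0,
    "HADS": 5.0,
    "PMI": 468.0,
}

#: score column and change orientation (+1: followup - baseline).
INSTRUMENT_ORIENTATION: dict[str, tuple[str, int]] = {
    "MCRI": ("MCRI", +1),
    "ODI": ("ODI_pct", -1),
    "EQ5D": ("EQ5D_index", +1),
    "NPRS": ("NPRS", -1),
    "HADS": ("HADS_total", -1),
    "PMI": ("PMI", -1),
}

INTERVALS: tuple[str, ...] = ("M0-M3", "M0-M6", "M0-M9", "M0-M12")


def dichotomize_pgic(pgic: float | np.ndarray) -> np.ndarray | bool:
    """Satisfactory self-perceived improvement: PGIC >= 6 on the 1-7 scale."""
    arr = np.asarray(pgic, float)
    out = arr >= 6
    return bool(out) if np.isscalar(pgic) or arr.ndim == 0 else out


@dataclass(frozen=True)
class ClassificationResult:
    """Responder classification of a change score against the anchor."""

    instrument: str
    interval: str
    cutoff: float
    tp: int
    fn: int
    fp: int
    tn: int
    auc: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("negative confusion counts")
        if not (0 <= self.auc <= 1):
            raise ValueError("AUC outside [0, 1]")

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def display(self) -> dict:
        """Rates rounded to the 0.1% used for reporting."""
        return {
            "instrument": self.instrument,
            "interval": self.interval,
            "cutoff": self.cutoff,
            "tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn,
            "sensitivity_pct": round(100 * self.sensitivity, 1),
            "specificity_pct": round(100 * self.specificity, 1),
            "auc": round(self.auc, 3),
        }


def change_table(scored: pd.DataFrame) -> pd.DataFrame:
    """Improvement-oriented change records per patient and interval.

    ``scored`` holds one row per (patient_id, visit) with the score columns
    (MCRI, ODI_pct, EQ5D_index, NPRS, HADS_total, PMI) and PGIC.  A change
    is emitted only when both endpoints are observed for that instrument;
    the anchor comes from the follow-up visit (available-case throughout).
    """
    wide = scored.set_index(["patient_id", "visit"])
    base = wide.xs("M0", level="visit")
    rows = []
    for interval in INTERVALS:
        fu_visit = interval.split("-")[1]
        try:
            fu = wide.xs(fu_visit, level="visit")
        except KeyError:
            continue
        common = base.index.intersection(fu.index)
        for pid in common:
            rec = {"patient_id": pid, "interval": interval}
            for name, (col, orient) in INSTRUMENT_ORIENTATION.items():
                if col not in scored.columns:
                    continue
                b, f = base.at[pid, col], fu.at[pid, col]
                rec[name] = orient * (f - b) if pd.notna(b) and pd.notna(f) else np.nan
            pg = fu.at[pid, "PGIC"] if "PGIC" in fu.columns else np.nan
            rec["PGIC"] = pg
            rec["satisfied"] = bool(pg >= 6) if pd.notna(pg) else np.nan
            rows.append(rec)
    return pd.DataFrame(rows)


def _two_classes(changes: np.ndarray, satisfied: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    changes = np.asarray(changes, float)
    satisfied = np.asarray(satisfied)
    keep = ~(np.isnan(changes) | pd.isna(satisfied))
    changes, satisfied = changes[keep], satisfied[keep].astype(bool)
    if satisfied.all() or (~satisfied).all():
        raise ValueError("need at least one satisfied and one unsatisfied record")
    return changes, satisfied


def confusion_metrics(
    changes: np.ndarray,
    satisfied: np.ndarray,
    cutoff: float,
    instrument: str = "",
    interval: str = "",
) -> ClassificationResult:
    """Classify improved iff change >= cutoff and cross-tabulate vs anchor."""
    changes, satisfied = _two_classes(changes, satisfied)
    improved = changes >= cutoff
    return ClassificationResult(
        instrument,
        interval,
        float(cutoff),
        tp=int((improved & satisfied).sum()),
        fn=int((~improved & satisfied).sum()),
        fp=int((improved & ~satisfied).sum()),
        tn=int((~improved & ~satisfied).sum()),
        auc=roc_auc(changes, satisfied),
    )


def roc_auc(changes: np.ndarray, satisfied: np.ndarray) -> float:
    """Mann-Whitney AUC: P(change_satisfied > change_unsatisfied) + half ties.

    Computed from average ranks, which equals both the all-pairs count with
    half credit for ties and trapezoidal integration of the ROC curve.
    """
    changes, satisfied = _two_classes(changes, satisfied)
    n1, n0 = int(satisfied.sum()), int((~satisfied).sum())
    ranks = stats.rankdata(changes)
    u = ranks[satisfied].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def optimal_cutoff(
    changes: np.ndarray,
    satisfied: np.ndarray,
    instrument: str = "",
    interval: str = "",
) -> ClassificationResult:
    """Youden-optimal responder cutoff.

    Candidate cutoffs are the midpoints between adjacent distinct change
    values plus the two extremes; the winner maximizes
    sensitivity + specificity, ties resolved toward higher sensitivity and
    then toward the smaller cutoff.
    """
    changes, satisfied = _two_classes(changes, satisfied)
    distinct = np.unique(changes)
    candidates = np.concatenate(
        [[-np.inf], (distinct[:-1] + distinct[1:]) / 2, [np.inf]]
    )
    best = None
    for c in candidates:
        improved = changes >= c
        tp = (improved & satisfied).sum()
        tn = (~improved & ~satisfied).sum()
        sens = tp / satisfied.sum()
        spec = tn / (~satisfied).sum()
        key = (sens + spec, sens, -c)
        if best is None or key > best[0]:
            best = (key, c)
    return confusion_metrics(changes, satisfied, best[1], instrument, interval)


@dataclass(frozen=True)
class JTResult:
    statistic: float
    z: float
    p_value: float
    method: str
    alternative: str


def _jt_statistic(groups: list[np.ndarray]) -> float:
    jt = 0.0
    for a, b in combinations(groups, 2):
        diff = b[None, :] - a[:, None]
        jt += (diff > 0).sum() + 0.5 * (diff == 0).sum()
    return float(jt)


def jonckheere_terpstra(
    groups: list[np.ndarray],
    alternative: str = "increasing",
    method: str = "asymptotic",
    n_resamples: int = 100_000,
    seed: int = 0,
) -> JTResult:
    """Jonckheere-Terpstra test for an ordered location trend across groups.

    The statistic sums Mann-Whitney counts over all ordered group pairs
    (half credit for ties).  ``method='asymptotic'`` uses the normal
    approximation with the tie-corrected variance; ``'exact'`` enumerates
    every assignment of the pooled observations to the group sizes (small
    samples); ``'permutation'`` draws ``n_resamples`` random shuffles.  The
    default alternative is an increasing trend; 'decreasing' and
    'two-sided' are available.
    """
    groups = [np.asarray(g, float)[~np.isnan(np.asarray(g, float))] for g in groups]
    groups = [g for g in groups if len(g)]
    if len(groups) < 2:
        raise ValueError("need at least two non-empty ordered groups")
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    N = len(pooled)
    jt = _jt_statistic(groups)
    mean = (N**2 - sum(n**2 for n in sizes)) / 4.0

    _, tie_counts = np.unique(pooled, return_counts=True)
    n_terms = np.array(sizes, dtype=float)
    t_terms = tie_counts.astype(float)
    v1 = (
        N * (N - 1) * (2 * N + 5)
        - (n_terms * (n_terms - 1) * (2 * n_terms + 5)).sum()
        - (t_terms * (t_terms - 1) * (2 * t_terms + 5)).sum()
    ) / 72.0
    v2 = (
        (n_terms * (n_terms - 1) * (n_terms - 2)).sum()
        * (t_terms * (t_terms - 1) * (t_terms - 2)).sum()
        / (36.0 * N * (N - 1) * (N - 2))
    )
    v3 = (
        (n_terms * (n_terms - 1)).sum()
        * (t_terms * (t_terms - 1)).sum()
        / (8.0 * N * (N - 1))
    )
    var = v1 + v2 + v3
    z = 0.0 if var <= 0 else (jt - mean) / np.sqrt(var)

    if method == "asymptotic":
        if alternative == "increasing":
            p = float(stats.norm.sf(z))
        elif alternative == "decreasing":
            p = float(stats.norm.cdf(z))
        else:
            p = float(2 * stats.norm.sf(abs(z)))
        return JTResult(jt, float(z), p, "asymptotic", alternative)

    def stat_of(assign: list[np.ndarray]) -> float:
        return _jt_statistic(assign)

    if method == "exact":
        total, extreme = 0, 0
        idx = np.arange(N)

        def recurse(remaining: np.ndarray, gi: int, chosen: list[np.ndarray]):
            nonlocal total, extreme
            if gi == len(sizes) - 1:
                parts = chosen + [remaining]
                s = stat_of([pooled[p_] for p_ in parts])
                total += 1
                cmp = s
                if alternative == "increasing":
                    extreme += cmp >= jt - 1e-12
                elif alternative == "decreasing":
                    extreme += cmp <= jt + 1e-12
                else:
                    extreme += abs(cmp - mean) >= abs(jt - mean) - 1e-12
                return
            for comb in combinations(range(len(remaining)), sizes[gi]):
                mask = np.zeros(len(remaining), dtype=bool)
                mask[list(comb)] = True
                recurse(remaining[~mask], gi + 1, chosen + [remaining[mask]])

        recurse(idx, 0, [])
        return JTResult(jt, float(z), extreme / total, "exact", alternative)

    if method == "permutation":
        rng = np.random.default_rng(seed)
        extreme = 0
        bounds = np.cumsum(sizes)[:-1]
        for _ in range(n_resamples):
            perm = rng.permutation(pooled)
            s = stat_of(np.split(perm, bounds))
            if alternative == "increasing":
                extreme += s >= jt - 1e-12
            elif alternative == "decreasing":
                extreme += s <= jt + 1e-12
            else:
                extreme += abs(s - mean) >= abs(jt - mean) - 1e-12
        return JTResult(jt, float(z), (extreme + 1) / (n_resamples + 1), "permutation", alternative)

    raise ValueError(f"unknown method {method!r}")


def correlation_report(
    scored: pd.DataFrame,
    visit: str,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[tuple[str, str], CorrelationSummary]]:
    """Per-visit Spearman correlation matrix of the index and instruments.

    Returns (rho matrix, display matrix with significance stars, detailed
    summaries per pair).  Stars: ** for p < 0.01, *** for p < 0.001.
    """
    sub = scored[scored["visit"] == visit]
    if len(sub) < 4:
        raise ValueError(f"fewer than 4 records at visit {visit}")
    names = [n for n, (col, _) in INSTRUMENT_ORIENTATION.items() if col in sub.columns]
    rho = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    disp = pd.DataFrame("", index=names, columns=names)
    np.fill_diagonal(disp.values, "1")
    details: dict[tuple[str, str], CorrelationSummary] = {}
    for a, b in combinations(names, 2):
        ca, cb = INSTRUMENT_ORIENTATION[a][0], INSTRUMENT_ORIENTATION[b][0]
        summ = spearman_ci(sub[ca].to_numpy(float), sub[cb].to_numpy(float))
        details[(a, b)] = summ
        rho.loc[a, b] = rho.loc[b, a] = summ.estimate
        stars = "***" if summ.p_value < 0.001 else "**" if summ.p_value < 0.01 else ""
        disp.loc[a, b] = disp.loc[b, a] = f"{summ.estimate:.3f} {stars}".strip()
    return rho, disp, details
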