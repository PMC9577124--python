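"""Evaluation statistics: AUC with bootstrap CI, permutation tests, balanced
accuracy, linearly weighted kappa, score binning, case aggregation,
Kaplan-Meier curves and Cox proportional-hazards summaries.

Conventions follow the evaluation protocol of outcome-supervised TMA scoring:
AUC confidence intervals use 1000 case-level bootstrap resamples (2.5/97.5
percentiles); two predictors on the same samples are compared with a paired
permutation test on |delta AUC| (1000 label-preserving swaps, add-one
smoothing); agreement between ordinal graders uses Cohen's kappa with linear
disagreement weights ``|i - j| / (k - 1)``; continuous risk scores are
reported per 0.1 units of change in Cox models so a [0, 1] score spans a
0-10 range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from lifelines import CoxPHFitter, KaplanMeierFitter

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix2:
    """Binary confusion matrix; rows are truth (low/high), columns prediction."""

    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self) -> None:
        if min(self.tn, self.fp, self.fn, self.tp) < 0:
            raise ValueError("counts must be non-negative")
        if self.tn + self.fp + self.fn + self.tp == 0:
            raise ValueError("confusion matrix is empty")


@dataclass(frozen=True)
class SurvivalInput:
    """Per-case survival data: time, event flag, and a score or group."""

    time_years: np.ndarray
    event: np.ndarray
    score: np.ndarray
    age: Optional[np.ndarray] = None
    psa: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time_years, dtype=float)
        if (t < 0).any():
            raise ValueError("survival times must be >= 0")
        if len(t) == 0:
            raise ValueError("empty survival input")


def balanced_accuracy(cm: ConfusionMatrix2) -> float:
    """Mean of sensitivity and specificity."""
    if cm.tp + cm.fn == 0 or cm.tn + cm.fp == 0:
        raise ValueError("balanced accuracy undefined with an empty class")
    sens = cm.tp / (cm.tp + cm.fn)
    spec = cm.tn / (cm.tn + cm.fp)
    return (sens + spec) / 2.0


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based two-sample AUC with half credit for ties."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def auc_bootstrap_ci(
    scores: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 1000,
    rng: Optional[np.random.Generator] = None,
    case_ids: Optional[Sequence] = None,
) -> tuple[float, float, float]:
    """Point AUC and a percentile bootstrap 95% CI.

    Resampling is at case level by default: when ``case_ids`` is given, whole
    cases are resampled with replacement so within-case correlation between
    spots is respected; otherwise each sample is its own case. Resamples that
    lose one class entirely are redrawn.
    """
    rng = np.random.default_rng() if rng is None else rng
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    point = auc(scores, labels)

    if case_ids is None:
        groups = [np.array([i]) for i in range(len(scores))]
    else:
        case_ids = np.asarray(case_ids)
        groups = [np.flatnonzero(case_ids == c) for c in pd.unique(case_ids)]
    n_groups = len(groups)

    stats = np.empty(n_boot)
    for b in range(n_boot):
        for _ in range(1000):
            pick = rng.integers(0, n_groups, size=n_groups)
            idx = np.concatenate([groups[g] for g in pick])
            if len(np.unique(labels[idx])) == 2:
                break
        else:  # pragma: no cover - pathological single-class cohorts
            raise ValueError("bootstrap cannot find a two-class resample")
        stats[b] = roc_auc_score(labels[idx], scores[idx])
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return point, float(lo), float(hi)


def auc_permutation_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[int],
    n_perm: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Two-sided paired permutation test for a difference in AUC.

    The null swaps the two predictors' scores independently per sample; the
    p-value is the add-one-smoothed fraction of permuted |delta AUC| at least
    as large as observed. Scores must be paired on identical samples.
    """
    rng = np.random.default_rng() if rng is None else rng
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if a.shape != b.shape or a.shape != labels.shape:
        raise ValueError("permutation test requires paired scores and labels")
    observed = abs(auc(a, labels) - auc(b, labels))
    count = 0
    for _ in range(n_perm):
        swap = rng.random(len(a)) < 0.5
        pa = np.where(swap, b, a)
        pb = np.where(swap, a, b)
        delta = abs(roc_auc_score(labels, pa) - roc_auc_score(labels, pb))
        if delta >= observed - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def weighted_kappa(matrix: Sequence[Sequence[float]]) -> float:
    """Cohen's kappa with linear disagreement weights on a square count matrix.

    Weights are ``|i - j| / (k - 1)`` — the block distance in the confusion
    matrix divided by the maximum block distance. Equals unweighted kappa for
    k = 2 and is invariant to rescaling the whole matrix.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"weighted kappa requires a square matrix, got {m.shape}")
    k = m.shape[0]
    if k < 2:
        raise ValueError("need at least 2 categories")
    n = m.sum()
    if n <= 0:
        raise ValueError("empty matrix")
    w = np.abs(np.subtract.outer(np.arange(k), np.arange(k))) / (k - 1)
    expected = np.outer(m.sum(axis=1), m.sum(axis=0)) / n
    expected_disagreement = (w * expected).sum()
    if expected_disagreement <= 0:
        raise ValueError("degenerate marginals: expected disagreement is zero")
    return float(1.0 - (w * m).sum() / expected_disagreement)


def bin_pcai(scores: Sequence[float], n_bins: int = 7) -> tuple[np.ndarray, list[str]]:
    """Equal-width bins of a [0, 1] score, right-closed at 1.0.

    Returns integer bin indices and their labels ("0.0-0.2", ...). The study
    uses 7 groups for survival curves and 5 segments for grader comparison.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size and (scores.min() < 0 or scores.max() > 1):
        raise ValueError("scores must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.minimum(np.digitize(scores, edges[1:-1], right=False), n_bins - 1)
    labels = [f"{edges[i]:.1f}-{edges[i + 1]:.1f}" for i in range(n_bins)]
    logger.debug("bin edges: %s", edges)
    return idx, labels


def case_score(spot_scores: Sequence[float]) -> float:
    """Aggregate spot scores to a case score: the maximum."""
    scores = [s for s in spot_scores if s is not None and np.isfinite(s)]
    if not scores:
        raise ValueError("no assessable spots for this case")
    return float(max(scores))


def km_curve(surv: SurvivalInput, groups: Optional[Sequence] = None) -> dict[str, pd.DataFrame]:
    """Product-limit survival estimate per group.

    ``groups`` defaults to ``surv.score`` treated as categorical. Each group's
    table has columns time, survival and at_risk; empty groups are dropped
    with a warning.
    """
    groups = surv.score if groups is None else np.asarray(groups)
    out: dict[str, pd.DataFrame] = {}
    for g in pd.unique(groups):
        sel = groups == g
        if not sel.any():
            logger.warning("group %s empty; dropped from KM", g)
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(surv.time_years[sel], surv.event[sel])
        table = kmf.event_table
        df = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.values,
                "survival": kmf.survival_function_.iloc[:, 0].values,
                "at_risk": table["at_risk"].reindex(kmf.survival_function_.index).values,
            }
        )
        out[str(g)] = df
    return out


@dataclass(frozen=True)
class CoxResult:
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    concordance: float
    per_unit: float


def cox_hr(
    surv: SurvivalInput,
    unit: float = 0.1,
    adjust: Sequence[str] = (),
) -> CoxResult:
    """Cox proportional-hazards fit of the score against the outcome.

    The score is divided by ``unit`` before fitting, so the hazard ratio is
    per ``unit`` of score (0.1 for a [0, 1] index, 0.5 for ISUP — both give a
    0-10 covariate range). ``adjust`` may list "age" and/or "psa", which must
    then be present in ``surv``. Raises when no events are present or the
    fit fails to converge.
    """
    if not np.asarray(surv.event).any():
        raise ValueError("Cox model requires at least one event")
    data = {"time": surv.time_years, "event": np.asarray(surv.event, dtype=int)}
    data["score"] = np.asarray(surv.score, dtype=float) / unit
    for name in adjust:
        values = getattr(surv, name, None)
        if values is None:
            raise ValueError(f"adjustment covariate {name!r} missing from survival input")
        data[name] = np.asarray(values, dtype=float)
    df = pd.DataFrame(data)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines raises various convergence errors
        raise RuntimeError(f"Cox fit failed: {exc}") from exc
    summary = cph.summary.loc["score"]
    return CoxResult(
        hazard_ratio=float(summary["exp(coef)"]),
        ci_low=float(summary["exp(coef) lower 95%"]),
        ci_high=float(summary["exp(coef) upper 95%"]),
        p_value=float(summary["p"]),
        concordance=float(cph.concordance_index_),
        per_unit=unit,
    )


def evaluation_report(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float = 0.5,
    n_boot: int = 1000,
    rng: Optional[np.random.Generator] = None,
    case_ids: Optional[Sequence] = None,
) -> dict:
    """Classification summary: AUC + CI, balanced accuracy, confusion matrix."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    point, lo, hi = auc_bootstrap_ci(scores, labels, n_boot=n_boot, rng=rng, case_ids=case_ids)
    pred = (scores >= threshold).astype(int)
    cm = ConfusionMatrix2(
        tn=int(((labels == 0) & (pred == 0)).sum()),
        fp=int(((labels == 0) & (pred == 1)).sum()),
        fn=int(((labels == 1) & (pred == 0)).sum()),
        tp=int(((labels == 1) & (pred == 1)).sum()),
    )
    return {
        "auc": point,
        "auc_ci": [lo, hi],
        "balanced_accuracy": balanced_accuracy(cm),
        "confusion_matrix": [cm.tn, cm.fp, cm.fn, cm.tp],
        "n": int(len(labels)),
    }
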