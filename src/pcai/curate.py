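"""Two-stage label curation: denoising, pseudo-labeling, TMA-balanced drafts.

TMA spots are tiny (~0.6 mm) cores, so a spot can be sampled at a location
unrepresentative of the whole prostate, and event-free cases with short
follow-up cannot be confirmed low risk. The curation pipeline addresses both:

1. **Denoising** — a stage-1 ("prototype") model is trained on the raw
   labels; samples whose stage-1 predicted probability of their own label
   falls below a disagreement threshold are discarded as likely
   unrepresentative. Denoising never relabels, it only removes.
2. **Pseudo-labeling** — event-free cases with follow-up of at most 5 years
   ("possible low risk") are added as low-risk per TMA, longest follow-up
   first, until that TMA reaches label balance or candidates run out.
3. **TMA-balanced drafting** — before each epoch an equal number of high- and
   low-risk samples is drawn from every TMA, so the model cannot profit from
   associating TMA-wide staining or thickness quirks with outcome.

Stage 2 retrains the same architecture on the curated set. Test sets are
never pseudo-labeled; test-set denoising produces the separate "cleaned"
evaluation which is always reported next to the raw one, since removing
samples the stage-1 model found hard can flatter the metrics.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from . import milnet
from .cohort import CaseRecord, LabelMode, RiskValue, assign_risk_label, is_possible_low_risk
from .preprocess import BagBuilder, ColorJitter, ScaleSpec

logger = logging.getLogger(__name__)

HIGH, LOW = "high", "low"


@dataclass(frozen=True)
class CurationConfig:
    """Knobs of the curation stage."""

    #: discard a sample when the stage-1 probability of its label is below
    #: this. For a *calibrated* prototype the threshold must exceed the
    #: expected unrepresentative-spot rate (a flipped spot's posterior label
    #: probability is about that rate), hence a default well above it; an
    #: overconfident deep prototype can use a much smaller value.
    denoise_disagreement_threshold: float = 0.3
    pseudo_label_enabled: bool = True
    draft_with_replacement: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.denoise_disagreement_threshold <= 1:
            raise ValueError("denoise_disagreement_threshold must be in [0, 1]")


@dataclass(frozen=True)
class LabeledSample:
    """One spot/case with a binary risk label."""

    sample_id: str
    tma_id: str
    label: str  # "high" | "low"

    def __post_init__(self) -> None:
        if self.label not in (HIGH, LOW):
            raise ValueError(f"label must be high/low, got {self.label!r}")


@dataclass(frozen=True)
class Candidate:
    """A possible-low-risk case: event-free, follow-up <= 5 years."""

    sample_id: str
    tma_id: str
    follow_up_years: float


@dataclass
class CuratedDataset:
    """Bookkeeping of one curation stage."""

    kept: list[LabeledSample]
    discarded: list[dict] = field(default_factory=list)
    pseudo_labeled: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        kept_ids = {s.sample_id for s in self.kept}
        disc_ids = {d["sample_id"] for d in self.discarded}
        if kept_ids & disc_ids:
            raise ValueError("kept and discarded sets overlap")

    def label_counts(self) -> dict[str, int]:
        counts = {HIGH: 0, LOW: 0}
        for s in self.kept:
            counts[s.label] += 1
        return counts

    def by_tma(self) -> dict[str, list[LabeledSample]]:
        groups: dict[str, list[LabeledSample]] = defaultdict(list)
        for s in self.kept:
            groups[s.tma_id].append(s)
        return dict(groups)

    def report(self) -> dict:
        """Label totals and per-TMA counts, the shape of a curation summary."""
        counts = self.label_counts()
        total = sum(counts.values())
        per_tma = {
            tma: {
                HIGH: sum(1 for s in group if s.label == HIGH),
                LOW: sum(1 for s in group if s.label == LOW),
            }
            for tma, group in sorted(self.by_tma().items())
        }
        return {
            "n_samples": total,
            "fraction_high": counts[HIGH] / total if total else float("nan"),
            "fraction_low": counts[LOW] / total if total else float("nan"),
            "n_discarded": len(self.discarded),
            "n_pseudo_labeled": len(self.pseudo_labeled),
            "per_tma": per_tma,
        }


def samples_from_cases(
    cases: Sequence[CaseRecord], mode: LabelMode | str
) -> tuple[list[LabeledSample], list[Candidate]]:
    """Split cases into labeled samples and pseudo-label candidates.

    Cases with an undefined label under ``mode`` are dropped from the labeled
    set; among those, the event-free short-follow-up ones become candidates.
    """
    labeled: list[LabeledSample] = []
    candidates: list[Candidate] = []
    for case in cases:
        value = assign_risk_label(case, mode).value
        if value is not RiskValue.UNDEFINED:
            labeled.append(LabeledSample(case.case_id, case.tma_id, value.value))
        elif is_possible_low_risk(case):
            candidates.append(
                Candidate(case.case_id, case.tma_id, float(case.follow_up_years))
            )
    return labeled, candidates


# ---------------------------------------------------------------------------
# Stage operations
# ---------------------------------------------------------------------------


def denoise(
    samples: Sequence[LabeledSample],
    stage1_scores: Mapping[str, float],
    config: CurationConfig = CurationConfig(),
) -> CuratedDataset:
    """Discard samples whose stage-1 prediction disagrees with their label.

    ``stage1_scores`` maps sample id to the predicted probability of the
    *high* class; a sample is discarded iff the predicted probability of its
    own label is below the disagreement threshold. With threshold 0 nothing
    is discarded. Raises ``KeyError`` if a sample lacks a score.
    """
    kept: list[LabeledSample] = []
    discarded: list[dict] = []
    thr = config.denoise_disagreement_threshold
    for s in samples:
        if s.sample_id not in stage1_scores:
            raise KeyError(f"no stage-1 score for sample {s.sample_id}")
        p_high = float(stage1_scores[s.sample_id])
        p_label = p_high if s.label == HIGH else 1.0 - p_high
        if p_label < thr:
            discarded.append(
                {
                    "sample_id": s.sample_id,
                    "tma_id": s.tma_id,
                    "label": s.label,
                    "p_label": p_label,
                    "reason": f"stage-1 P(label)={p_label:.3f} < {thr}",
                }
            )
        else:
            kept.append(s)
    logger.info("denoise: kept %d, discarded %d", len(kept), len(discarded))
    return CuratedDataset(kept=kept, discarded=discarded)


def pseudo_label(
    samples: Sequence[LabeledSample],
    candidates: Sequence[Candidate],
) -> CuratedDataset:
    """Add possible-low-risk candidates as low, per TMA, to approach balance.

    Candidates must have follow-up <= 5 years (they are unconfirmed by
    definition); within each TMA they are added in descending follow-up
    (ties broken by sample id) until the low count reaches the high count or
    the candidate pool is depleted.
    """
    for cand in candidates:
        if cand.follow_up_years > 5.0:
            raise ValueError(
                f"candidate {cand.sample_id} has follow-up "
                f"{cand.follow_up_years} > 5 y: already a confirmable low"
            )
    kept = list(samples)
    added: list[str] = []
    by_tma_counts: dict[str, dict[str, int]] = defaultdict(lambda: {HIGH: 0, LOW: 0})
    for s in samples:
        by_tma_counts[s.tma_id][s.label] += 1
    cands_by_tma: dict[str, list[Candidate]] = defaultdict(list)
    for cand in candidates:
        cands_by_tma[cand.tma_id].append(cand)
    for tma_id, cands in sorted(cands_by_tma.items()):
        counts = by_tma_counts[tma_id]
        pool = sorted(cands, key=lambda c: (-c.follow_up_years, c.sample_id))
        for cand in pool:
            if counts[LOW] >= counts[HIGH]:
                break
            kept.append(LabeledSample(cand.sample_id, tma_id, LOW))
            added.append(cand.sample_id)
            counts[LOW] += 1
    logger.info("pseudo-label: added %d low-risk samples", len(added))
    return CuratedDataset(kept=kept, pseudo_labeled=added)


def tma_balanced_draft(
    samples: Sequence[LabeledSample],
    rng: np.random.Generator,
    with_replacement: bool = False,
) -> list[str]:
    """Per-TMA class-balanced epoch draft.

    From each TMA, ``k = min(#high, #low)`` samples are drawn from each class
    (without replacement by default); TMAs missing a class contribute
    nothing. Redrawn fresh every epoch.
    """
    drafted: list[str] = []
    groups: dict[str, dict[str, list[str]]] = defaultdict(lambda: {HIGH: [], LOW: []})
    for s in samples:
        groups[s.tma_id][s.label].append(s.sample_id)
    for tma_id in sorted(groups):
        highs, lows = groups[tma_id][HIGH], groups[tma_id][LOW]
        k = min(len(highs), len(lows))
        if k == 0:
            continue
        for pool in (highs, lows):
            picked = rng.choice(pool, size=k, replace=with_replacement)
            drafted.extend(str(p) for p in picked)
    return drafted


def global_balanced_draft(
    samples: Sequence[LabeledSample],
    rng: np.random.Generator,
    with_replacement: bool = False,
) -> list[str]:
    """Class-balanced draft ignoring TMA membership (the ablation baseline)."""
    highs = [s.sample_id for s in samples if s.label == HIGH]
    lows = [s.sample_id for s in samples if s.label == LOW]
    k = min(len(highs), len(lows))
    drafted: list[str] = []
    for pool in (highs, lows):
        picked = rng.choice(pool, size=k, replace=with_replacement)
        drafted.extend(str(p) for p in picked)
    return drafted


# ---------------------------------------------------------------------------
# Two-stage training
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainSettings:
    """Optimisation and sampling settings shared by both stages."""

    epochs_stage1: int = 15
    epochs_stage2: int = 20
    #: optional fixed optimizer-step budgets; when set they override the
    #: epoch counts, keeping sampling schemes with different draft sizes at
    #: equal compute (used by the ablation harness)
    steps_stage1: Optional[int] = None
    steps_stage2: Optional[int] = None
    batch_size: int = 8
    lr: float = 1e-3
    balancing: str = "tma"  # "tma" | "global"
    n_augment: int = 1
    jitter: ColorJitter = ColorJitter()
    tissue_threshold: float = 0.25


@dataclass
class TwoStageResult:
    stage1_model: milnet.MILModel
    stage2_models: dict[float, milnet.MILModel]
    curated: CuratedDataset
    denoised: CuratedDataset
    report: dict


def _make_draft_fn(
    samples: list[LabeledSample],
    index_of: Mapping[str, int],
    balancing: str,
    with_replacement: bool,
) -> Callable[[int, np.random.Generator], list[int]]:
    draft = tma_balanced_draft if balancing == "tma" else global_balanced_draft
    if balancing not in ("tma", "global"):
        raise ValueError(f"unknown balancing scheme {balancing!r}")

    def fn(epoch: int, rng: np.random.Generator) -> list[int]:
        ids = draft(samples, rng, with_replacement)
        return [index_of[i] for i in ids]

    return fn


def two_stage_train(
    builders: Mapping[str, BagBuilder],
    train_cases: Sequence[CaseRecord],
    test_ids: set[str],
    scale_specs: Mapping[float, ScaleSpec],
    model_spec: milnet.ModelSpec,
    settings: TrainSettings = TrainSettings(),
    curation: CurationConfig = CurationConfig(),
    rng: Optional[np.random.Generator] = None,
    stage1_scale: Optional[float] = None,
) -> TwoStageResult:
    """Train stage 1, curate, train stage 2 — the full label-curation loop.

    ``builders`` maps sample id to its cached bag builder; ``test_ids`` is the
    frozen test split, used only for the leakage guard (training raises if
    any test case appears among the training cases). Stage 1 trains a single
    prototype model on ``stage1_scale`` (default: the highest-weight scale
    present); stage 2 trains one model per scale on the curated labels.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    train_id_set = {c.case_id for c in train_cases}
    overlap = train_id_set & set(test_ids)
    if overlap:
        raise ValueError(f"train/test leakage: {sorted(overlap)[:5]} in both splits")

    labeled, candidates = samples_from_cases(train_cases, LabelMode.TRAIN)
    labeled = [s for s in labeled if s.sample_id in builders]
    candidates = [c for c in candidates if c.sample_id in builders]

    if stage1_scale is None:
        stage1_scale = max(
            scale_specs, key=lambda s: milnet.DEFAULT_ENSEMBLE_WEIGHTS.get(s, 0.0)
        )
    spec1 = scale_specs[stage1_scale]

    # ---- stage 1: prototype on raw labels --------------------------------
    ids = [s.sample_id for s in labeled]
    index_of = {sid: i for i, sid in enumerate(ids)}
    stage1_bags = _LazyBags([builders[i] for i in ids], spec1, rng)
    labels = np.array([1 if s.label == HIGH else 0 for s in labeled])
    draft_fn = _make_draft_fn(labeled, index_of, settings.balancing,
                              curation.draft_with_replacement)
    stage1_model = milnet.train(
        stage1_bags, labels, model_spec, settings.epochs_stage1, rng,
        batch_size=settings.batch_size, lr=settings.lr, draft_fn=draft_fn,
        total_steps=settings.steps_stage1,
    )

    # ---- curation ---------------------------------------------------------
    eval_bags = [builders[i].eval_bag(spec1) for i in ids]
    scores = stage1_model.predict_bags(eval_bags)
    score_map = dict(zip(ids, scores))
    denoised = denoise(labeled, score_map, curation)
    if curation.pseudo_label_enabled:
        pseudo = pseudo_label(denoised.kept, candidates)
        curated = CuratedDataset(
            kept=pseudo.kept,
            discarded=denoised.discarded,
            pseudo_labeled=pseudo.pseudo_labeled,
        )
    else:
        curated = denoised

    # ---- stage 2: per-scale models on curated labels ----------------------
    ids2 = [s.sample_id for s in curated.kept]
    index2 = {sid: i for i, sid in enumerate(ids2)}
    labels2 = np.array([1 if s.label == HIGH else 0 for s in curated.kept])
    draft2 = _make_draft_fn(curated.kept, index2, settings.balancing,
                            curation.draft_with_replacement)
    stage2_models: dict[float, milnet.MILModel] = {}
    for scale, spec in scale_specs.items():
        bags2 = _LazyBags([builders[i] for i in ids2], spec, rng)
        stage2_models[scale] = milnet.train(
            bags2, labels2, model_spec, settings.epochs_stage2, rng,
            batch_size=settings.batch_size, lr=settings.lr, draft_fn=draft2,
            total_steps=settings.steps_stage2,
        )

    report = {
        "raw": CuratedDataset(kept=list(labeled)).report(),
        "denoised": denoised.report(),
        "curated": curated.report(),
        "stage1_scale": stage1_scale,
    }
    return TwoStageResult(
        stage1_model=stage1_model,
        stage2_models=stage2_models,
        curated=curated,
        denoised=denoised,
        report=report,
    )


class _LazyBags:
    """Sequence façade that draws a fresh augmented bag on every access."""

    def __init__(self, builders: Sequence[BagBuilder], spec: ScaleSpec, rng):
        self._builders = builders
        self._spec = spec
        self._rng = rng

    def __len__(self) -> int:
        return len(self._builders)

    def __getitem__(self, i: int):
        return self._builders[i].sample_bag(self._spec, self._rng)
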