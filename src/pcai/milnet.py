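"""Attention-based multiple-instance-learning scorer.

One spot is a *bag* of patches. An encoder maps each patch to a feature
vector, an attention head assigns each instance a normalised weight, the
weighted sum of features is the bag embedding, and a decoder turns the
embedding into a 2-class probability whose positive component is the risk
score. Three such models, one per magnification scale, are combined in a
linear ensemble of probabilities with weights 0.25 (scale 1.0), 0.25 (scale
0.25) and 0.5 (scale 0.5) into the final PCAI score in [0, 1].

The attention head is a one-hidden-layer network (64 units, mish activation,
batch norm) producing one logit per instance, softmax-normalised over the
bag; the decoder has hidden widths 768 and 16 with the same activation and
normalisation. The encoder is injectable through a registry; the package
ships a compact three-block convolutional encoder sized for CPU training on
small synthetic patches. Larger pretrained backbones can be registered by
the caller.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from . import nn
from .preprocess import (
    ColorJitter,
    InstanceBag,
    NoInstancesError,
    ScaleSpec,
    SpotImage,
    build_model_bag,
)

logger = logging.getLogger(__name__)

#: ensemble weights over scale factors; optimised against the training set
#: in the original study and kept as the package default
DEFAULT_ENSEMBLE_WEIGHTS: dict[float, float] = {1.0: 0.25, 0.25: 0.25, 0.5: 0.5}


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyper-parameters of one single-scale MIL model."""

    encoder: str = "tiny-cnn"
    feature_dim: int = 16
    encoder_channels: tuple[int, ...] = (8, 16)
    attention_hidden: int = 64
    decoder_hidden: tuple[int, int] = (768, 16)
    n_classes: int = 2
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


@dataclass
class SpotScore:
    """Per-scale and ensemble scores for one spot."""

    spot_id: str
    case_id: str
    scale_scores: dict[float, float]
    pcai: float
    attention_weights: dict[float, np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Encoders
# ---------------------------------------------------------------------------


class TinyCNNEncoder(nn.Module):
    """Three stride-2 conv blocks with mish, global average pooled.

    Sized for small patches (>= 15 px); feature width is configurable.
    """

    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        c1, c2 = spec.encoder_channels
        self.conv1 = nn.Conv2d(3, c1, kernel=3, stride=2, rng=rng)
        self.conv2 = nn.Conv2d(c1, c2, kernel=3, stride=2, rng=rng)
        self.conv3 = nn.Conv2d(c2, spec.feature_dim, kernel=3, stride=2, rng=rng)
        self.feature_dim = spec.feature_dim

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        h = self.conv1(x).mish()
        h = self.conv2(h).mish()
        h = self.conv3(h).mish()
        n, c = h.shape[0], h.shape[1]
        return h.reshape(n, c, -1).mean(axis=2)


ENCODERS: dict[str, Callable[[ModelSpec, np.random.Generator], nn.Module]] = {
    "tiny-cnn": TinyCNNEncoder,
}


def register_encoder(name: str, builder: Callable[[ModelSpec, np.random.Generator], nn.Module]) -> None:
    """Register an encoder builder, e.g. a wrapper around a pretrained backbone."""
    ENCODERS[name] = builder


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


class _MLPHead(nn.Module):
    """Linear -> batchnorm -> mish blocks followed by a linear output."""

    def __init__(self, widths: Sequence[int], n_out: int, rng: np.random.Generator):
        layers: list[nn.Module] = []
        norms: list[nn.Module] = []
        for n_in, n_hidden in zip(widths[:-1], widths[1:]):
            layers.append(nn.Linear(n_in, n_hidden, rng))
            norms.append(nn.BatchNorm1d(n_hidden))
        self.hidden = layers
        self.norms = norms
        self.out = nn.Linear(widths[-1], n_out, rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        for lin, bn in zip(self.hidden, self.norms):
            x = bn(lin(x)).mish()
        return self.out(x)


class MILModel(nn.Module):
    """Encoder + attention pooling + decoder for one scale."""

    def __init__(self, spec: ModelSpec):
        if spec.encoder not in ENCODERS:
            raise ValueError(
                f"unknown encoder {spec.encoder!r}; available: {sorted(ENCODERS)}"
            )
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        self.encoder = ENCODERS[spec.encoder](spec, rng)
        f = spec.feature_dim
        self.attention = _MLPHead([f, spec.attention_hidden], 1, rng)
        self.decoder = _MLPHead([f, *spec.decoder_hidden], spec.n_classes, rng)
        self.loss_history: list[float] = []

    # -- pieces ---------------------------------------------------------------
    def encode_instances(self, bag: InstanceBag | np.ndarray) -> nn.Tensor:
        """One feature vector per instance; deterministic given the weights."""
        patches = bag.as_array() if isinstance(bag, InstanceBag) else np.asarray(bag)
        if patches.ndim != 4:
            raise ValueError(f"expected (n, H, W, 3) patches, got shape {patches.shape}")
        if patches.shape[0] == 0:
            raise ValueError("empty bag")
        x = nn.Tensor(patches.transpose(0, 3, 1, 2))  # NHWC -> NCHW
        return self.encoder(x)

    def attention_pool(self, features: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        """Softmax attention weights and the weighted-sum bag embedding.

        Weights sum to one over the bag; the embedding is invariant to
        instance permutation while the weights permute along.
        """
        if features.shape[0] == 0:
            raise ValueError("attention_pool requires at least one instance")
        logits = self.attention(features)  # (n, 1)
        weights = nn.softmax(logits.T, axis=1).T  # softmax over instances
        embedding = weights.T @ features  # (1, f)
        return embedding, weights

    def forward_bag(self, bag: InstanceBag | np.ndarray) -> tuple[nn.Tensor, nn.Tensor]:
        features = self.encode_instances(bag)
        return self.attention_pool(features)

    # -- inference ------------------------------------------------------------
    def predict_bags(
        self, bags: Sequence[InstanceBag | np.ndarray], return_attention: bool = False
    ):
        """Positive-class probability per bag (evaluation mode)."""
        self.set_training(False)
        scores = np.empty(len(bags))
        attention: list[np.ndarray] = []
        for i, bag in enumerate(bags):
            embedding, weights = self.forward_bag(bag)
            logits = self.decoder(embedding)
            probs = nn.softmax(logits, axis=1).data[0]
            scores[i] = probs[1]
            if return_attention:
                attention.append(weights.data.ravel().copy())
        if return_attention:
            return scores, attention
        return scores


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def train(
    bags: Sequence[InstanceBag | np.ndarray],
    labels: Sequence[int],
    spec: ModelSpec,
    epochs: int,
    rng: np.random.Generator,
    batch_size: int = 8,
    lr: float = 1e-3,
    draft_fn: Optional[Callable[[int, np.random.Generator], Sequence[int]]] = None,
    model: Optional[MILModel] = None,
    total_steps: Optional[int] = None,
) -> MILModel:
    """Train a single-scale MIL model with cross-entropy.

    ``draft_fn(epoch, rng) -> indices`` supplies the per-epoch training draft
    (e.g. TMA-balanced sampling); by default every bag is used each epoch.
    When ``total_steps`` is given, training runs for that many optimizer
    steps instead of a fixed epoch count (fresh drafts are still drawn
    per pass), which keeps comparisons between sampling schemes with
    different draft sizes at equal compute.
    Raises ``ValueError`` before any update if an epoch draft is single-class.
    """
    labels = np.asarray(labels, dtype=int)
    if len(bags) != len(labels):
        raise ValueError("bags and labels differ in length")
    model = model if model is not None else MILModel(spec)
    optimizer = nn.Adam(model.parameters(), lr=lr)

    steps_done = 0
    epoch_budget = epochs if total_steps is None else 10_000
    for epoch in range(epoch_budget):
        if total_steps is not None and steps_done >= total_steps:
            break
        indices = (
            np.asarray(draft_fn(epoch, rng), dtype=int)
            if draft_fn is not None
            else np.arange(len(bags))
        )
        drafted = labels[indices]
        if len(np.unique(drafted)) < 2:
            raise ValueError(
                f"epoch {epoch}: training draft contains a single class; "
                "check labels or the drafting scheme"
            )
        order = rng.permutation(len(indices))
        indices = indices[order]
        model.set_training(True)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(indices), batch_size):
            if total_steps is not None and steps_done >= total_steps:
                break
            batch = indices[start : start + batch_size]
            embeddings = []
            for i in batch:
                embedding, _ = model.forward_bag(bags[i])
                embeddings.append(embedding)
            stacked = embeddings[0]
            for e in embeddings[1:]:
                # concatenate along the batch axis via summed zero-padding
                stacked = _concat_rows(stacked, e)
            logits = model.decoder(stacked)
            loss = nn.cross_entropy(logits, labels[batch])
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data)
            n_batches += 1
            steps_done += 1
        mean_loss = epoch_loss / max(n_batches, 1)
        model.loss_history.append(mean_loss)
        logger.debug("epoch %d: loss %.4f (%d bags)", epoch, mean_loss, len(indices))
    return model


def _concat_rows(a: nn.Tensor, b: nn.Tensor) -> nn.Tensor:
    """Differentiable row-wise concatenation of two 2-D tensors."""
    na, nb = a.shape[0], b.shape[0]
    data = np.concatenate([a.data, b.data], axis=0)

    def backward(g):
        if a.requires_grad:
            a._accum(g[:na])
        if b.requires_grad:
            b._accum(g[na:])

    return a._make(data, (a, b), backward)


# ---------------------------------------------------------------------------
# Multi-scale prediction
# ---------------------------------------------------------------------------


def combine_scores(
    scale_scores: Mapping[float, float],
    weights: Mapping[float, float] = DEFAULT_ENSEMBLE_WEIGHTS,
) -> float:
    """Linear ensemble of per-scale probabilities.

    Weights are restricted to the scales present and re-normalised to sum to
    one, so a reduced scale set remains a convex combination.
    """
    present = {s: weights[s] for s in scale_scores}
    total = sum(present.values())
    if total <= 0:
        raise ValueError("ensemble weights must be positive for the scales present")
    return float(sum(scale_scores[s] * w / total for s, w in present.items()))


def predict_spot(
    spot: SpotImage,
    models: Mapping[float, MILModel],
    scale_specs: Mapping[float, ScaleSpec],
    ensemble_weights: Mapping[float, float] = DEFAULT_ENSEMBLE_WEIGHTS,
    tissue_threshold: Optional[float] = 0.25,
    min_patches: int = 1,
) -> Optional[SpotScore]:
    """Score one spot with the per-scale models and the linear ensemble.

    Returns ``None`` (spot unassessable, to be excluded from metrics) when
    any scale yields no instances or fewer than ``min_patches`` survive.
    """
    scale_scores: dict[float, float] = {}
    attention: dict[float, np.ndarray] = {}
    for scale, model in models.items():
        spec = scale_specs[scale]
        try:
            bag = build_model_bag(spot, spec, rng=None, tissue_threshold=tissue_threshold)
        except (NoInstancesError, ValueError) as exc:
            logger.info("spot %s unassessable at scale %s: %s", spot.spot_id, scale, exc)
            return None
        if len(bag) < min_patches:
            logger.info(
                "spot %s unassessable: %d < %d patches at scale %s",
                spot.spot_id, len(bag), min_patches, scale,
            )
            return None
        scores, attn = model.predict_bags([bag], return_attention=True)
        scale_scores[scale] = float(scores[0])
        attention[scale] = attn[0]
    pcai = combine_scores(scale_scores, ensemble_weights)
    return SpotScore(
        spot_id=spot.spot_id,
        case_id=spot.case_id,
        scale_scores=scale_scores,
        pcai=pcai,
        attention_weights=attention,
    )


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------


def save_model(model: MILModel, path: str | Path) -> None:
    """Write weights as ``<path>.npz`` plus a ``<path>.json`` architecture sidecar."""
    path = Path(path)
    np.savez(path.parent / (path.name + ".npz"), **model.state_arrays())
    (path.parent / (path.name + ".json")).write_text(model.spec.to_json())


def load_model(path: str | Path) -> MILModel:
    path = Path(path)
    if path.name.endswith(".npz") or path.name.endswith(".json"):
        path = path.parent / path.name.rsplit(".", 1)[0]
    raw = json.loads((path.parent / (path.name + ".json")).read_text())
    raw["encoder_channels"] = tuple(raw["encoder_channels"])
    raw["decoder_hidden"] = tuple(raw["decoder_hidden"])
    spec = ModelSpec(**raw)
    model = MILModel(spec)
    with np.load(path.parent / (path.name + ".npz")) as data:
        model.load_state_arrays(dict(data))
    return model
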