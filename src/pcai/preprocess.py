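"""Spot-image preprocessing and instance (patch) creation.

Images are linear-light RGB in [0, 1]. Before feature extraction each spot is
mapped to optical density, ``OD = -ln(max(I, 1e-3))``, because stain quantity
is proportional to absorbance, not transmission: the log transform expands the
dynamic range where haematoxylin and eosin are concentrated and compresses the
uninformative bright background. Per-spot, per-channel standardisation in OD
space then removes global staining intensity, which is what makes the model
portable across slides and scanners.

Multiple-instance bags are built by laying a non-overlapping grid of square
patches over the (optionally down-scaled) spot, with a uniform random grid
offset per epoch, and dropping patches with too little tissue.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage import color as _skcolor
from skimage.transform import downscale_local_mean, resize

logger = logging.getLogger(__name__)

#: transmission floor for the optical-density transform
OD_FLOOR = 1e-3

#: OD of the floor, the largest attainable value: -ln(1e-3)
OD_MAX = -float(np.log(OD_FLOOR))

#: mean-OD threshold above which a pixel counts as tissue
DEFAULT_TISSUE_OD_THRESHOLD = 0.15

#: minimum tissue fraction for a patch to enter a bag
DEFAULT_PATCH_TISSUE_FRACTION = 0.25


class NoInstancesError(RuntimeError):
    """Raised when a spot yields no patches that pass the tissue filter."""


@dataclass(frozen=True)
class SpotImage:
    """One TMA spot raster tied to a case and a TMA."""

    pixels: np.ndarray  # H x W x 3, linear light in [0, 1]
    spot_id: str
    case_id: str
    tma_id: str
    microns_per_pixel: float = 0.25

    def __post_init__(self) -> None:
        px = self.pixels
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected HxWx3 array, got shape {px.shape}")
        if px.min() < 0 or px.max() > 1:
            raise ValueError("pixel values must lie in [0, 1]")


@dataclass(frozen=True)
class ScaleSpec:
    """One entry of the multi-scale instance grid.

    ``scale_factor`` re-samples the spot before tiling (1.0 keeps full
    resolution), ``patch_px`` is the tile side in pixels after re-sampling.
    """

    scale_factor: float
    patch_px: int

    def __post_init__(self) -> None:
        if not 0 < self.scale_factor <= 1:
            raise ValueError("scale_factor must be in (0, 1]")
        if self.patch_px < 1:
            raise ValueError("patch_px must be positive")


#: the three full-resolution scales used at 0.25 um/px: 40x fine chromatin
#: texture, 10x glandular architecture, 20x in between
FULL_RESOLUTION_SCALES = (
    ScaleSpec(1.0, 224),
    ScaleSpec(0.25, 224),
    ScaleSpec(0.5, 352),
)


@dataclass
class InstanceBag:
    """The set of fixed-size patches from one spot at one scale.

    ``origins`` are 0-based top-left corners of half-open tiles in the
    *re-sampled* image's pixel space.
    """

    patches: list[np.ndarray]
    origins: list[tuple[int, int]]
    scale: ScaleSpec
    spot_id: str = ""

    def __len__(self) -> int:
        return len(self.patches)

    def as_array(self) -> np.ndarray:
        return np.stack(self.patches)


# ---------------------------------------------------------------------------
# Optical density
# ---------------------------------------------------------------------------


def od_transform(image: np.ndarray) -> np.ndarray:
    """Map linear-light values in [0, 1] to optical density.

    ``OD = -ln(max(I, 1e-3))``; output lies in [0, -ln(1e-3)] and is monotone
    decreasing in the input. Natural log; any other base is an affine rescale
    absorbed by the subsequent normalisation.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.min() < 0 or image.max() > 1:
        raise ValueError("od_transform expects values in [0, 1]; normalize first")
    return -np.log(np.maximum(image, OD_FLOOR))


def tissue_mask(
    image: np.ndarray, od_threshold: float = DEFAULT_TISSUE_OD_THRESHOLD
) -> np.ndarray:
    """Boolean mask of pixels whose channel-mean OD exceeds the threshold."""
    od = od_transform(image)
    return od.mean(axis=-1) > od_threshold


def tissue_fraction(
    image: np.ndarray, od_threshold: float = DEFAULT_TISSUE_OD_THRESHOLD
) -> float:
    """Fraction of pixels classified as tissue (bright background excluded)."""
    return float(tissue_mask(image, od_threshold).mean())


def normalize_od(
    od_image: np.ndarray, mask: Optional[np.ndarray] = None
) -> np.ndarray:
    """Standardise an OD image to zero mean, unit SD per channel.

    Statistics are computed per spot and per channel over tissue pixels only
    (``mask``); the whole image is then shifted and scaled so the result is
    invariant to affine re-scalings of the OD values (and hence to global
    exposure changes of the underlying linear image). A constant channel is
    mapped to zeros with a warning.
    """
    od_image = np.asarray(od_image, dtype=np.float64)
    if mask is None:
        mask = np.ones(od_image.shape[:2], dtype=bool)
    if not mask.any():
        raise ValueError("empty tissue mask: cannot normalize")
    out = np.empty_like(od_image)
    values = od_image[mask]  # (n_tissue, 3)
    for c in range(od_image.shape[2]):
        mu = values[:, c].mean()
        sd = values[:, c].std()
        if sd < 1e-12:
            warnings.warn(f"channel {c} constant over tissue; normalized to zeros")
            out[..., c] = 0.0
        else:
            out[..., c] = (od_image[..., c] - mu) / sd
    return out


def preprocess_spot(
    image: np.ndarray, od_threshold: float = DEFAULT_TISSUE_OD_THRESHOLD
) -> np.ndarray:
    """Full preprocessing: OD transform + per-spot tissue-masked standardisation."""
    mask = tissue_mask(image, od_threshold)
    return normalize_od(od_transform(image), mask)


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ColorJitter:
    """Uniform per-spot colour perturbation ranges (fractions of 1).

    Defaults: brightness +/-2%, contrast +/-5%, saturation +/-20%, hue +/-5%
    (of a full hue revolution), applied in that order before preprocessing.
    """

    brightness: float = 0.02
    contrast: float = 0.05
    saturation: float = 0.20
    hue: float = 0.05

    def draw_factors(self, rng: np.random.Generator) -> tuple[float, float, float, float]:
        return (
            rng.uniform(-self.brightness, self.brightness),
            rng.uniform(-self.contrast, self.contrast),
            rng.uniform(-self.saturation, self.saturation),
            rng.uniform(-self.hue, self.hue),
        )


def augment_color(
    image: np.ndarray,
    rng: np.random.Generator,
    jitter: ColorJitter = ColorJitter(),
) -> np.ndarray:
    """Randomly jitter brightness, contrast, saturation and hue of a spot.

    Factors are drawn uniformly in the configured ranges and applied in the
    order brightness -> contrast -> saturation -> hue; the output is clipped
    to [0, 1]. With all ranges zero this is the identity.
    """
    b, c, s, h = jitter.draw_factors(rng)
    out = np.asarray(image, dtype=np.float64)
    out = out * (1.0 + b)
    mean = out.mean()
    out = (out - mean) * (1.0 + c) + mean
    gray = out.mean(axis=-1, keepdims=True)
    out = gray + (out - gray) * (1.0 + s)
    out = np.clip(out, 0.0, 1.0)
    if h != 0.0:
        hsv = _skcolor.rgb2hsv(out)
        hsv[..., 0] = (hsv[..., 0] + h) % 1.0
        out = _skcolor.hsv2rgb(hsv)
    return np.clip(out, 0.0, 1.0)


def dihedral_variant(patch: np.ndarray, k: int) -> np.ndarray:
    """Return element ``k`` of the dihedral group D4 applied to a square patch.

    ``k`` in 0..7: k % 4 quarter-turn rotations, preceded by a horizontal
    mirror when k >= 4. k = 0 is the identity.
    """
    if not 0 <= k <= 7:
        raise ValueError(f"dihedral index must be in 0..7, got {k}")
    if patch.shape[0] != patch.shape[1]:
        raise ValueError("dihedral variants require a square patch")
    out = patch[:, ::-1] if k >= 4 else patch
    return np.rot90(out, k % 4)


def dihedral_inverse(k: int) -> int:
    """Index of the group inverse of dihedral element ``k``."""
    if not 0 <= k <= 7:
        raise ValueError(f"dihedral index must be in 0..7, got {k}")
    if k < 4:
        return (4 - k) % 4
    return k  # reflections are involutions in this indexing


# ---------------------------------------------------------------------------
# Instance creation
# ---------------------------------------------------------------------------


def _rescale(image: np.ndarray, scale_factor: float) -> np.ndarray:
    if scale_factor == 1.0:
        return np.asarray(image, dtype=np.float64)
    inv = 1.0 / scale_factor
    if abs(inv - round(inv)) < 1e-9:
        # exact area averaging for integer down-scale factors
        f = int(round(inv))
        h, w = image.shape[:2]
        image = image[: (h // f) * f, : (w // f) * f]
        return downscale_local_mean(np.asarray(image, dtype=np.float64), (f, f, 1))
    h, w = image.shape[:2]
    new_shape = (int(h * scale_factor), int(w * scale_factor), image.shape[2])
    return resize(image, new_shape, anti_aliasing=True, preserve_range=True)


def make_instances(
    spot: SpotImage,
    spec: ScaleSpec,
    rng: Optional[np.random.Generator] = None,
    offset: Optional[tuple[int, int]] = None,
    tissue_threshold: Optional[float] = DEFAULT_PATCH_TISSUE_FRACTION,
    od_threshold: float = DEFAULT_TISSUE_OD_THRESHOLD,
) -> InstanceBag:
    """Tile a spot into a bag of patches at one scale.

    The spot is re-sampled by ``spec.scale_factor`` (area averaging), a
    non-overlapping grid of ``patch_px`` tiles is laid out with a uniform
    random offset in [0, patch_px) per axis (or the explicit ``offset``), and
    tiles whose tissue fraction falls below ``tissue_threshold`` are dropped
    (pass ``None`` to keep everything).

    Raises ``NoInstancesError`` if no tile survives, and ``ValueError`` if the
    image cannot contain even one tile.
    """
    image = _rescale(spot.pixels, spec.scale_factor)
    h, w = image.shape[:2]
    p = spec.patch_px
    if h < p or w < p:
        raise ValueError(
            f"spot {spot.spot_id}: image {h}x{w} at scale {spec.scale_factor} "
            f"cannot contain a {p} px patch"
        )
    if offset is None:
        if rng is None:
            offset = (0, 0)
        else:
            offset = (int(rng.integers(0, p)), int(rng.integers(0, p)))
    oy, ox = offset

    patches: list[np.ndarray] = []
    origins: list[tuple[int, int]] = []
    for y in range(oy, h - p + 1, p):
        for x in range(ox, w - p + 1, p):
            tile = image[y : y + p, x : x + p]
            if tissue_threshold is not None:
                if tissue_fraction(np.clip(tile, 0, 1), od_threshold) < tissue_threshold:
                    continue
            patches.append(tile)
            origins.append((y, x))
    if not patches:
        raise NoInstancesError(
            f"spot {spot.spot_id}: no instances at scale {spec.scale_factor} "
            f"(grid offset {offset}, tissue threshold {tissue_threshold})"
        )
    return InstanceBag(patches=patches, origins=origins, scale=spec, spot_id=spot.spot_id)


class BagBuilder:
    """Cached per-spot bag construction for epoch-loop training.

    Colour augmentation and OD normalisation are the expensive parts of bag
    building, so a small pool of pre-augmented, pre-normalised variants is
    computed once per spot and scale (variant 0 is unaugmented); per-epoch
    randomness then reduces to picking a variant, a fresh grid offset and
    dihedral flips, which are cheap slicing operations.
    """

    def __init__(
        self,
        spot: SpotImage,
        specs: Sequence[ScaleSpec],
        rng: Optional[np.random.Generator] = None,
        n_augment: int = 0,
        jitter: ColorJitter = ColorJitter(),
        tissue_threshold: float = DEFAULT_PATCH_TISSUE_FRACTION,
        od_threshold: float = DEFAULT_TISSUE_OD_THRESHOLD,
    ):
        self.spot_id = spot.spot_id
        self.tissue_threshold = tissue_threshold
        variants = [spot.pixels]
        for _ in range(n_augment):
            if rng is None:
                raise ValueError("augmented variants require an rng")
            variants.append(augment_color(spot.pixels, rng, jitter))
        # per scale: list of (normalized float32 image, tissue mask)
        self._cache: dict[ScaleSpec, list[tuple[np.ndarray, np.ndarray]]] = {}
        for spec in specs:
            entries = []
            for pixels in variants:
                linear = np.clip(_rescale(pixels, spec.scale_factor), 0.0, 1.0)
                mask = tissue_mask(linear, od_threshold)
                if not mask.any():
                    raise NoInstancesError(f"spot {spot.spot_id}: no tissue pixels")
                normalized = normalize_od(od_transform(linear), mask)
                entries.append((normalized.astype(np.float32), mask))
            self._cache[spec] = entries

    def _tile(
        self,
        spec: ScaleSpec,
        variant: int,
        offset: tuple[int, int],
        rng: Optional[np.random.Generator],
    ) -> InstanceBag:
        normalized, mask = self._cache[spec][variant]
        h, w = normalized.shape[:2]
        p = spec.patch_px
        if h < p or w < p:
            raise ValueError(
                f"spot {self.spot_id}: image {h}x{w} cannot contain a {p} px patch"
            )
        oy, ox = offset
        patches, origins = [], []
        for y in range(oy, h - p + 1, p):
            for x in range(ox, w - p + 1, p):
                if mask[y : y + p, x : x + p].mean() < self.tissue_threshold:
                    continue
                tile = normalized[y : y + p, x : x + p]
                if rng is not None:
                    tile = dihedral_variant(tile, int(rng.integers(0, 8)))
                patches.append(tile)
                origins.append((y, x))
        if not patches:
            raise NoInstancesError(
                f"spot {self.spot_id}: no instances at scale {spec.scale_factor}"
            )
        return InstanceBag(patches=patches, origins=origins, scale=spec, spot_id=self.spot_id)

    def sample_bag(self, spec: ScaleSpec, rng: np.random.Generator) -> InstanceBag:
        """Random variant, grid offset and dihedral flips — one training draw."""
        variant = int(rng.integers(0, len(self._cache[spec])))
        p = spec.patch_px
        offset = (int(rng.integers(0, p)), int(rng.integers(0, p)))
        try:
            return self._tile(spec, variant, offset, rng)
        except NoInstancesError:
            return self._tile(spec, variant, (0, 0), rng)

    def eval_bag(self, spec: ScaleSpec) -> InstanceBag:
        """Deterministic bag: unaugmented variant, zero offset, no flips."""
        return self._tile(spec, 0, (0, 0), None)


def build_model_bag(
    spot: SpotImage,
    spec: ScaleSpec,
    rng: Optional[np.random.Generator] = None,
    jitter: Optional[ColorJitter] = None,
    augment_dihedral: bool = False,
    tissue_threshold: Optional[float] = DEFAULT_PATCH_TISSUE_FRACTION,
    od_threshold: float = DEFAULT_TISSUE_OD_THRESHOLD,
) -> InstanceBag:
    """Produce the bag of *model-ready* patches for one spot at one scale.

    Order of operations follows the training recipe: optional per-spot colour
    jitter on the linear image, re-sampling, tissue filtering of grid tiles on
    the linear image, then OD transform + per-spot standardisation; patches
    are cut from the standardised image at the surviving tile origins, with an
    optional random dihedral variant per patch.
    """
    pixels = spot.pixels
    if jitter is not None:
        if rng is None:
            raise ValueError("colour jitter requires an rng")
        pixels = augment_color(pixels, rng, jitter)

    image = _rescale(pixels, spec.scale_factor)
    h, w = image.shape[:2]
    p = spec.patch_px
    if h < p or w < p:
        raise ValueError(
            f"spot {spot.spot_id}: image {h}x{w} at scale {spec.scale_factor} "
            f"cannot contain a {p} px patch"
        )
    offset = (0, 0) if rng is None else (int(rng.integers(0, p)), int(rng.integers(0, p)))
    oy, ox = offset

    linear = np.clip(image, 0.0, 1.0)
    mask = tissue_mask(linear, od_threshold)
    if not mask.any():
        raise NoInstancesError(f"spot {spot.spot_id}: no tissue pixels")
    normalized = normalize_od(od_transform(linear), mask)

    patches: list[np.ndarray] = []
    origins: list[tuple[int, int]] = []
    for y in range(oy, h - p + 1, p):
        for x in range(ox, w - p + 1, p):
            if tissue_threshold is not None:
                if mask[y : y + p, x : x + p].mean() < tissue_threshold:
                    continue
            tile = normalized[y : y + p, x : x + p]
            if augment_dihedral and rng is not None:
                tile = dihedral_variant(tile, int(rng.integers(0, 8)))
            patches.append(tile)
            origins.append((y, x))
    if not patches:
        raise NoInstancesError(
            f"spot {spot.spot_id}: no instances at scale {spec.scale_factor} "
            f"(grid offset {offset}, tissue threshold {tissue_threshold})"
        )
    return InstanceBag(patches=patches, origins=origins, scale=spec, spot_id=spot.spot_id)
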