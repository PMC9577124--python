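"""A fully synthetic TMA world with planted, measurable structure.

The generator emulates the statistical skeleton of a prostatectomy TMA
biobank: cases grouped into TMAs, right-censored follow-up driven by a latent
aggressiveness, and one spot image per case whose texture carries the latent.

* **Survival.** Each case has a latent risk ``r`` in [0, 1] drawn from a
  bimodal Beta mixture tilted by its TMA's risk mix (indolent vs aggressive
  disease). The bad-outcome time is exponential with hazard
  ``lambda0 * exp(beta * r)``; censoring is uniform. ``lambda0`` is
  calibrated by root finding so the realised bad-outcome fraction matches the
  configured prevalence (default 23.7%).
* **Morphology.** Spots are rendered as a circular tissue disk with dark
  nuclei-like blobs on pink stroma. The planted statistic — the dark-pixel
  fraction of tissue — is monotone in latent risk with slope
  ``morphology_effect``, and is independently measurable, so it serves as an
  oracle for what any image model can learn.
* **Confounds.** Each TMA carries a per-channel additive stain shift and,
  optionally, a random blob-density offset (a staining/thickness analogue
  that survives per-spot OD normalisation). Offsets are independent of the
  TMA's risk mix, so with unbalanced TMAs they are spuriously predictive in
  an unbalanced training draft yet useless on held-out TMAs. With
  probability ``unrepresentative_rate`` a spot's morphology is drawn from the
  TMA's mirrored latent prior — the opposite risk's appearance — emulating a
  core punched at a non-representative location; this is the label noise the
  denoising stage exists to remove.

Ground truth (latents, render latents, TMA profiles) is written to a world
manifest that training code never reads.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .cohort import CaseRecord, write_cohort
from .preprocess import SpotImage

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of the synthetic TMA world; the seed fixes every output."""

    n_tmas: int = 8
    cases_per_tma: int = 40
    spot_px: int = 128
    #: slope of blob area fraction in latent risk (dimensionless)
    morphology_effect: float = 0.35
    #: blob area fraction of tissue at latent 0.5
    base_blob_fraction: float = 0.25
    #: max |additive per-channel stain shift| per TMA
    tma_stain_shift: float = 0.05
    #: half-range of the random per-TMA blob-density offset (a staining/
    #: thickness bias that survives per-spot OD normalisation); 0 disables it
    tma_density_bias: float = 0.0
    #: half-range of the random per-TMA blob-size factor around 1.0 (a
    #: thickness/sectioning signature: same planted area fraction rendered as
    #: fewer-but-larger or more-but-smaller nuclei); 0 disables it
    tma_blob_scale_range: float = 0.0
    #: probability that a spot is rendered from the opposite latent
    unrepresentative_rate: float = 0.0
    #: target fraction of cases with a bad outcome
    prevalence: float = 0.237
    #: log-hazard effect of one unit of latent risk
    log_hazard_beta: float = 10.0
    #: uniform censoring window (years)
    censor_low: float = 0.5
    censor_high: float = 12.0
    #: concentration of the Beta latent prior (< 1 is bimodal)
    latent_concentration: float = 0.8
    #: range of per-TMA risk-mix fractions
    risk_mix_range: tuple[float, float] = (0.25, 0.75)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("unrepresentative_rate", "prevalence"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if self.censor_high <= self.censor_low:
            raise ValueError("censor_high must exceed censor_low")


@dataclass(frozen=True)
class TMAProfile:
    """Per-TMA biases, drawn once and recorded in the world manifest."""

    tma_id: str
    stain_shift: tuple[float, float, float]
    density_offset: float
    risk_mix: float
    blob_scale: float = 1.0


@dataclass
class SyntheticWorld:
    """Cohort + ground truth; spot images are rendered lazily or up front."""

    config: WorldConfig
    cases: list[CaseRecord]
    tma_profiles: dict[str, TMAProfile]
    latents: dict[str, float]
    render_latents: dict[str, float]
    unrepresentative: dict[str, bool]
    spot_seeds: dict[str, int]

    def render_all(self) -> dict[str, SpotImage]:
        profiles = self.tma_profiles
        return {
            rec.case_id: render_spot(
                self.render_latents[rec.case_id],
                profiles[rec.tma_id],
                self.config,
                self.spot_seeds[rec.case_id],
                spot_id=f"spot_{rec.case_id}",
                case_id=rec.case_id,
            )
            for rec in self.cases
        }

    def manifest(self) -> dict:
        return {
            "config": asdict(self.config),
            "tma_profiles": {t: asdict(p) for t, p in self.tma_profiles.items()},
            "latents": self.latents,
            "render_latents": self.render_latents,
            "unrepresentative": self.unrepresentative,
            "spot_seeds": self.spot_seeds,
        }


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _calibrate_lambda0(latents: np.ndarray, config: WorldConfig) -> float:
    """Base hazard such that the expected bad-outcome fraction hits prevalence.

    With uniform censoring on [a, b] the per-case event probability has the
    closed form ``1 - (exp(-mu a) - exp(-mu b)) / (mu (b - a))`` for hazard
    ``mu``; the population mean is monotone in lambda0, so a bracketed root
    find suffices.
    """
    a, b = config.censor_low, config.censor_high
    beta = config.log_hazard_beta

    def expected_prevalence(lam0: float) -> float:
        mu = lam0 * np.exp(beta * latents)
        return float(np.mean(1.0 - (np.exp(-mu * a) - np.exp(-mu * b)) / (mu * (b - a))))

    lo, hi = 1e-12, 1e4
    p_lo, p_hi = expected_prevalence(lo), expected_prevalence(hi)
    if not p_lo < config.prevalence < p_hi:
        raise ValueError(
            f"prevalence {config.prevalence} unreachable with censoring "
            f"[{a}, {b}] y and beta {beta}: attainable range "
            f"({p_lo:.4f}, {p_hi:.4f})"
        )
    return brentq(lambda l: expected_prevalence(l) - config.prevalence, lo, hi)


def generate_cohort(config: WorldConfig) -> SyntheticWorld:
    """Generate cases, follow-up and ground-truth latents for the whole world.

    Deterministic in ``config`` (seed included); the bad-outcome fraction is
    calibrated to ``config.prevalence`` up to binomial noise.
    """
    root = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    n = config.n_tmas * config.cases_per_tma

    # per-TMA profiles
    profiles: dict[str, TMAProfile] = {}
    for t in range(config.n_tmas):
        tma_id = f"tma{t:02d}"
        risk_mix = float(rng.uniform(*config.risk_mix_range))
        shift = rng.uniform(-config.tma_stain_shift, config.tma_stain_shift, size=3)
        density_offset = float(
            rng.uniform(-config.tma_density_bias, config.tma_density_bias)
            if config.tma_density_bias
            else 0.0
        )
        blob_scale = float(
            1.0 + rng.uniform(-config.tma_blob_scale_range, config.tma_blob_scale_range)
            if config.tma_blob_scale_range
            else 1.0
        )
        profiles[tma_id] = TMAProfile(
            tma_id=tma_id,
            stain_shift=tuple(float(s) for s in shift),
            density_offset=density_offset,
            risk_mix=risk_mix,
            blob_scale=blob_scale,
        )

    tma_ids = np.repeat(sorted(profiles), config.cases_per_tma)
    mixes = np.array([profiles[t].risk_mix for t in tma_ids])
    c = config.latent_concentration
    latents = rng.beta(c * mixes, c * (1.0 - mixes))
    latents = np.clip(latents, 1e-6, 1 - 1e-6)

    lam0 = _calibrate_lambda0(latents, config)
    logger.info("calibrated base hazard lambda0 = %.3e", lam0)
    mu = lam0 * np.exp(config.log_hazard_beta * latents)
    event_time = rng.exponential(1.0 / mu)
    censor_time = rng.uniform(config.censor_low, config.censor_high, size=n)
    occurred = event_time <= censor_time
    follow_up = np.where(occurred, event_time, censor_time)

    # clinical covariates, loosely matched to a prostatectomy cohort
    age = np.clip(rng.normal(63.8, 7.0, size=n), 40, 88)
    psa = np.exp(rng.normal(np.log(6.9), 0.75, size=n))
    isup = np.clip(np.rint(1 + 4 * np.clip(latents + rng.normal(0, 0.15, n), 0, 1)), 1, 5)
    pt = np.where(rng.random(n) < expit(-1.2 + 2.2 * latents), 3.0, 2.0)

    p_pn = expit(-3.4 + 2.6 * latents)
    p_pv = expit(-3.0 + 2.6 * latents)
    pn = rng.random(n) < p_pn
    pv = rng.random(n) < p_pv
    pl = rng.random(n) < p_pv * 0.6
    pn_missing = rng.random(n) < 0.33
    pvl_missing = rng.random(n) < 0.31

    # attribute the composite event to BCR / metastasis / cancer death
    which = rng.choice(3, size=n, p=[0.82, 0.14, 0.04])

    # unrepresentative spots render morphology drawn from the case's
    # *mirrored* latent prior — the opposite risk's appearance, as if the
    # core had been punched in a non-representative region
    unrep = rng.random(n) < config.unrepresentative_rate
    mirrored = rng.beta(c * (1.0 - latents), c * latents)
    spot_ss = root.spawn(1 + n)[1:]

    cases: list[CaseRecord] = []
    latent_map: dict[str, float] = {}
    render_map: dict[str, float] = {}
    unrep_map: dict[str, bool] = {}
    seed_map: dict[str, int] = {}
    for i in range(n):
        case_id = f"case{i:05d}"
        ev = bool(occurred[i])
        t_ev = float(follow_up[i]) if ev else None
        cases.append(
            CaseRecord(
                case_id=case_id,
                tma_id=str(tma_ids[i]),
                age=float(age[i]),
                preop_psa=float(psa[i]),
                isup=float(isup[i]),
                pt_stage=float(pt[i]),
                pn_flag=None if pn_missing[i] else bool(pn[i]),
                pv_flag=None if pvl_missing[i] else bool(pv[i]),
                pl_flag=None if pvl_missing[i] else bool(pl[i]),
                follow_up_years=float(follow_up[i]),
                bcr_flag=ev and which[i] == 0,
                t_bcr=t_ev if ev and which[i] == 0 else None,
                met_flag=ev and which[i] == 1,
                t_met=t_ev if ev and which[i] == 1 else None,
                cdeath_flag=ev and which[i] == 2,
                t_cdeath=t_ev if ev and which[i] == 2 else None,
            )
        )
        latent_map[case_id] = float(latents[i])
        render_map[case_id] = float(mirrored[i]) if unrep[i] else float(latents[i])
        unrep_map[case_id] = bool(unrep[i])
        seed_map[case_id] = int(spot_ss[i].generate_state(1)[0] % (2**31))

    return SyntheticWorld(
        config=config,
        cases=cases,
        tma_profiles=profiles,
        latents=latent_map,
        render_latents=render_map,
        unrepresentative=unrep_map,
        spot_seeds=seed_map,
    )


# ---------------------------------------------------------------------------
# Spot rendering
# ---------------------------------------------------------------------------

_STROMA_RGB = np.array([0.89, 0.72, 0.83])
_NUCLEUS_RGB = np.array([0.35, 0.26, 0.52])
_BACKGROUND = 0.96

#: thresholds of the planted-statistic oracle (channel-mean linear light)
_TISSUE_CUTOFF = 0.85
_DARK_CUTOFF = 0.60


def blob_fraction_target(latent: float, config: WorldConfig, tma: Optional[TMAProfile] = None) -> float:
    """Blob area fraction planted for a given latent risk."""
    f = config.base_blob_fraction + config.morphology_effect * (latent - 0.5)
    if tma is not None:
        f += tma.density_offset
    return float(np.clip(f, 0.03, 0.65))


def render_spot(
    latent: float,
    tma: TMAProfile,
    config: WorldConfig,
    seed: int,
    spot_id: str = "spot",
    case_id: str = "case",
) -> SpotImage:
    """Render one spot: a tissue disk with latent-dependent nuclear blobs.

    Bit-identical for identical arguments. The TMA stain shift is applied
    additively to the tissue pixels' channels.
    """
    if not 0 <= latent <= 1:
        raise ValueError(f"latent must be in [0, 1], got {latent}")
    px = config.spot_px
    rng = np.random.default_rng(seed)

    image = np.full((px, px, 3), _BACKGROUND) + rng.normal(0, 0.008, (px, px, 1))
    yy, xx = np.mgrid[0:px, 0:px].astype(float)
    center = (px - 1) / 2.0
    radius = 0.46 * px
    disk = (yy - center) ** 2 + (xx - center) ** 2 <= radius**2

    stroma = _STROMA_RGB + rng.normal(0, 0.02, (px, px, 3))
    image[disk] = stroma[disk]

    # plant dark blobs at the target area fraction; the TMA blob-size factor
    # trades blob count against blob size at a fixed area fraction
    target = blob_fraction_target(latent, config, tma)
    scale = tma.blob_scale
    mean_blob_area = np.pi * (2.25 * scale) ** 2
    n_blobs = int(round(target * disk.sum() / mean_blob_area))
    for _ in range(n_blobs):
        rho = radius * np.sqrt(rng.random())
        phi = rng.random() * 2 * np.pi
        cy, cx = center + rho * np.sin(phi), center + rho * np.cos(phi)
        rb = rng.uniform(1.6, 2.9) * scale
        y0, y1 = int(max(cy - rb - 1, 0)), int(min(cy + rb + 2, px))
        x0, x1 = int(max(cx - rb - 1, 0)), int(min(cx + rb + 2, px))
        sub_y, sub_x = np.mgrid[y0:y1, x0:x1].astype(float)
        blob = (sub_y - cy) ** 2 + (sub_x - cx) ** 2 <= rb**2
        color = _NUCLEUS_RGB + rng.normal(0, 0.02, 3)
        region = image[y0:y1, x0:x1]
        region[blob] = color
        image[y0:y1, x0:x1] = region

    image[disk] += np.asarray(tma.stain_shift)
    image += rng.normal(0, 0.01, image.shape)
    image = np.clip(image, 0.0, 1.0)
    return SpotImage(
        pixels=image, spot_id=spot_id, case_id=case_id, tma_id=tma.tma_id,
        microns_per_pixel=1.0,
    )


def planted_statistic(image: SpotImage | np.ndarray) -> float:
    """Dark-pixel fraction of tissue — the independently measurable signal.

    Tissue: channel-mean below 0.85 (excludes the bright background); dark:
    channel-mean below 0.60 (the nuclear blobs). Returns 0 for a blank image.
    """
    pixels = image.pixels if isinstance(image, SpotImage) else np.asarray(image)
    gray = pixels.mean(axis=-1)
    tissue = gray < _TISSUE_CUTOFF
    if not tissue.any():
        return 0.0
    return float((gray[tissue] < _DARK_CUTOFF).mean())


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def write_world(world: SyntheticWorld, out_dir: str | Path, write_images: bool = True) -> None:
    """Write cohort table, spot PNGs + manifest TSV, and the ground-truth JSON.

    The ground-truth manifest (``world_manifest.json``) is for assertions and
    audits only; training code must never read it.
    """
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_cohort(world.cases, out_dir / "cohort.tsv")
    (out_dir / "world_manifest.json").write_text(
        json.dumps(world.manifest(), indent=1, sort_keys=True)
    )
    rows = ["spot_id\tcase_id\ttma_id\timage_path"]
    if write_images:
        (out_dir / "spots").mkdir(exist_ok=True)
        for case_id, spot in world.render_all().items():
            rel = f"spots/{spot.spot_id}.png"
            arr = np.clip(np.rint(spot.pixels * 255), 0, 255).astype(np.uint8)
            Image.fromarray(arr).save(out_dir / rel)
            rows.append(f"{spot.spot_id}\t{case_id}\t{spot.tma_id}\t{rel}")
    (out_dir / "spots.tsv").write_text("\n".join(rows) + "\n")
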