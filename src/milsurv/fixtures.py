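"""Synthetic fixtures: mock slides and feature bags with a planted,
parameterized prognostic signal driving right-censored survival.

Two generators cover the weak-supervision setting end to end:

* :func:`gen_feature_bags` — per-case instance embeddings in which a
  controlled fraction of instances is mean-shifted along a fixed
  direction; the per-case signal burden sets a log-linear hazard
  (proportional hazards, exponential by default) from which survival
  times and independent, rate-calibrated uniform censoring are drawn.
* :func:`gen_mock_slide` / :func:`gen_slide_cohort` — white-background
  slides with pink elliptical tissue blobs, an optional high-frequency
  "risk texture" region with known ground-truth masks, and survival
  driven by the risk-region area fraction.

Everything is fully deterministic from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from .evaluate import CaseRecord
from .features import EMBED_DIM, FeatureBag, PatchEncoder, encode_patches
from .model import SCALE_ORDER
from .wsi import PatchRef, SlideHandle, segment_tissue, tile_patches, read_patch

__all__ = [
    "FixtureConfig",
    "FixtureData",
    "gen_feature_bags",
    "MockSlide",
    "gen_mock_slide",
    "SlideCohort",
    "gen_slide_cohort",
    "slide_cohort_to_bags",
]

#: Baseline hazard: median survival of 36 months under no signal.
BASE_HAZARD = math.log(2.0) / 36.0


# ---------------------------------------------------------------------------
# survival simulation shared by both generators
# ---------------------------------------------------------------------------

def _draw_survival(risk: np.ndarray, rng: np.random.Generator,
                   base_hazard: float = BASE_HAZARD, shape: float = 1.0,
                   censor_rate: float = 0.0):
    """Proportional-hazards survival times with calibrated uniform censoring.

    ``T_i`` has survival ``exp(-lam_i t^shape)`` with
    ``lam_i = base_hazard * exp(risk_i)`` (exponential for shape=1).
    Censoring is uniform on ``[0, c_max]`` with ``c_max`` solved so the
    expected censored proportion, given the realized times, equals
    ``censor_rate``.
    """
    lam = base_hazard * np.exp(np.asarray(risk, dtype=float))
    u = rng.random(lam.size)
    T = (-np.log(u) / lam) ** (1.0 / shape)
    T = np.maximum(T, 0.05)
    if censor_rate <= 0:
        return T, np.ones(lam.size, dtype=int)

    def censored_frac(c):
        return float(np.minimum(T, c).mean() / c) - censor_rate

    c_max = brentq(censored_frac, 1e-9, float(T.max()) * 1e4)
    C = rng.random(lam.size) * c_max
    event = (T <= C).astype(int)
    time = np.minimum(T, C)
    return time, event


def _clinical(rng: np.random.Generator, n: int):
    ages = np.clip(rng.normal(62.0, 10.0, size=n), 25.0, 90.0)
    sexes = np.where(rng.random(n) < 0.5, "female", "male")
    return ages, sexes


# ---------------------------------------------------------------------------
# feature-bag fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for the feature-bag generator.

    ``signal_fraction`` is the cohort-mean fraction of signal instances
    per bag; per-case fractions are uniform on ``[0, 2*signal_fraction]``
    with the instance count taken exactly (``round(frac * bag_size)``).
    ``effect_beta`` is the log hazard ratio per standard deviation of
    the per-case signal fraction; ``effect_beta = 0`` makes survival
    independent of the bags by construction.  ``signal_shift`` is the
    embedding-space mean offset of signal instances along a fixed
    seeded unit direction (one independent direction and noise draw per
    scale, sharing the same latent case state).
    """

    n_cases: int = 300
    bag_size: int = 50
    signal_fraction: float = 0.1
    effect_beta: float = 2.0
    signal_shift: float = 2.0
    censor_rate: float = 0.3
    n_scales: int = 1
    seed: int = 7
    feature_dim: int = EMBED_DIM
    base_hazard: float = BASE_HAZARD
    weibull_shape: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.signal_fraction <= 1:
            raise ValueError("signal_fraction must lie in [0, 1]")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.effect_beta < 0 or self.signal_shift < 0:
            raise ValueError("effect sizes must be non-negative")
        if not 1 <= self.n_scales <= len(SCALE_ORDER):
            raise ValueError(f"n_scales must be 1..{len(SCALE_ORDER)}")

    @property
    def scales(self) -> Tuple[str, ...]:
        # highest magnifications first to drop: 1 scale -> 20x only
        return tuple(SCALE_ORDER[-self.n_scales:])


@dataclass
class FixtureData:
    bags: Dict[str, Dict[str, FeatureBag]]
    records: List[CaseRecord]
    signal_flags: Dict[str, Dict[str, np.ndarray]]  # case -> scale -> bool (B,)
    signal_fraction: np.ndarray                     # realized per-case fraction
    risk: np.ndarray                                # per-case log hazard ratio


def _grid_refs(case_id: str, scale: str, B: int) -> List[PatchRef]:
    w = 512
    cols = max(1, int(math.ceil(math.sqrt(B))))
    return [PatchRef(slide_id=f"{case_id}_s0", scale=scale,
                     x=(i % cols) * w, y=(i // cols) * w, w=w, h=w)
            for i in range(B)]


def gen_feature_bags(config: FixtureConfig) -> FixtureData:
    """Simulate feature bags with planted signal and censored survival.

    Background instances are standard normal in ``feature_dim``; signal
    instances are mean-shifted by ``signal_shift`` along a per-scale
    unit direction.  The per-case risk is
    ``effect_beta * (frac_c - mean) / sd`` over the realized signal
    fractions, and survival follows the proportional-hazards draw of
    :func:`_draw_survival`.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    D, B, n = cfg.feature_dim, cfg.bag_size, cfg.n_cases
    scales = cfg.scales
    directions = {}
    for s in scales:
        v = rng.normal(size=D)
        directions[s] = v / np.linalg.norm(v)

    frac_hi = 2.0 * cfg.signal_fraction
    phi = rng.uniform(0.0, frac_hi, size=n) if frac_hi > 0 else np.zeros(n)
    k_signal = np.round(phi * B).astype(int)
    frac = k_signal / B

    sd_ref = frac_hi / math.sqrt(12.0)  # sd of U(0, 2*signal_fraction)
    if cfg.effect_beta > 0 and sd_ref > 0:
        risk = cfg.effect_beta * (frac - cfg.signal_fraction) / sd_ref
    else:
        risk = np.zeros(n)

    time, event = _draw_survival(risk, rng, base_hazard=cfg.base_hazard,
                                 shape=cfg.weibull_shape,
                                 censor_rate=cfg.censor_rate)
    ages, sexes = _clinical(rng, n)

    bags: Dict[str, Dict[str, FeatureBag]] = {}
    flags: Dict[str, Dict[str, np.ndarray]] = {}
    records: List[CaseRecord] = []
    for i in range(n):
        cid = f"case_{i:04d}"
        bags[cid] = {}
        flags[cid] = {}
        for s in scales:
            feats = rng.normal(size=(B, D))
            is_signal = np.zeros(B, dtype=bool)
            is_signal[: k_signal[i]] = True
            perm = rng.permutation(B)
            is_signal = is_signal[perm]
            feats[is_signal] += cfg.signal_shift * directions[s]
            bags[cid][s] = FeatureBag(
                case_id=cid, scale=s, features=feats.astype(np.float32),
                patch_refs=_grid_refs(cid, s, B))
            flags[cid][s] = is_signal
        records.append(CaseRecord(
            case_id=cid, slide_ids=(f"{cid}_s0",), age=float(ages[i]),
            sex=str(sexes[i]), os_time=float(time[i]), os_event=int(event[i])))
    return FixtureData(bags=bags, records=records, signal_flags=flags,
                       signal_fraction=frac, risk=risk)


# ---------------------------------------------------------------------------
# mock slides
# ---------------------------------------------------------------------------

_TISSUE_RGB = np.array([225.0, 160.0, 185.0])   # pale H&E pink
_RISK_RGB_A = np.array([150.0, 60.0, 120.0])    # high-frequency checker
_RISK_RGB_B = np.array([205.0, 115.0, 160.0])   # both tones well saturated


@dataclass
class MockSlide:
    image: np.ndarray        # (H, W, 3) uint8
    tissue_mask: np.ndarray  # (H, W) bool, ground truth
    risk_mask: np.ndarray    # (H, W) bool
    slide_id: str = "mock"

    def as_slide(self, base_mag: float = 40.0) -> SlideHandle:
        return SlideHandle.from_array(self.image, id=self.slide_id,
                                      base_mag=base_mag)


def _inscribe_rect(tissue: np.ndarray, cy: float, cx: float,
                   half: int) -> Optional[Tuple[int, int, int, int]]:
    """Largest centered square (side 2*half, shrinking) fully in tissue."""
    H, W = tissue.shape
    while half >= 16:
        y0, y1 = int(cy - half), int(cy + half)
        x0, x1 = int(cx - half), int(cx + half)
        if 0 <= y0 and y1 <= H and 0 <= x0 and x1 <= W \
                and tissue[y0:y1, x0:x1].all():
            return (x0, y0, x1 - x0, y1 - y0)
        half = int(half * 0.85)
    return None


def gen_mock_slide(width: int = 2048, height: int = 2048,
                   n_tissue_blobs: int = 3,
                   risk_region=None, seed: int = 0,
                   risk_half_size: Optional[int] = None,
                   blob_axes: Tuple[float, float] = (0.12, 0.28)) -> MockSlide:
    """Mock slide: pink-textured elliptical tissue blobs on white.

    ``risk_region`` may be ``None``, an ``(x, y, w, h)`` rectangle (must
    lie fully inside tissue, else ``ValueError``), or ``"auto"`` to
    inscribe a square in the largest blob (side controlled by
    ``risk_half_size``).  The risk region is filled with a distinct
    high-frequency checker texture.  Masks are full resolution.
    """
    if width < 512 or height < 512:
        raise ValueError("slide dims must be >= 512")
    rng = np.random.default_rng(seed)
    from skimage.draw import ellipse

    tissue = np.zeros((height, width), dtype=bool)
    areas = []
    for _ in range(n_tissue_blobs):
        cy = rng.uniform(0.25, 0.75) * height
        cx = rng.uniform(0.25, 0.75) * width
        ry = rng.uniform(*blob_axes) * height
        rx = rng.uniform(*blob_axes) * width
        rr, cc = ellipse(cy, cx, ry, rx, shape=tissue.shape,
                         rotation=rng.uniform(0, np.pi))
        tissue[rr, cc] = True
        areas.append((len(rr), cy, cx, min(rx, ry)))

    image = np.full((height, width, 3), 255.0)
    noise = rng.normal(0.0, 8.0, size=(height, width, 1))
    image[tissue] = (_TISSUE_RGB + noise[tissue]).clip(0, 255)

    risk_mask = np.zeros_like(tissue)
    if risk_region is not None:
        if not tissue.any():
            raise ValueError("risk region requested but slide has no tissue")
        if isinstance(risk_region, str) and risk_region == "auto":
            _, cy, cx, r = max(areas)
            half = risk_half_size or int(r / math.sqrt(2.0) * 0.9)
            rect = _inscribe_rect(tissue, cy, cx, half)
            if rect is None:
                raise ValueError("could not inscribe a risk region in tissue")
        else:
            rect = tuple(int(v) for v in risk_region)
        x, y, w, h = rect
        if not tissue[y: y + h, x: x + w].all() or w <= 0 or h <= 0:
            raise ValueError("risk region must lie fully inside tissue")
        risk_mask[y: y + h, x: x + w] = True
        yy, xx = np.mgrid[y: y + h, x: x + w]
        checker = ((yy // 8) + (xx // 8)) % 2 == 0
        block = np.where(checker[..., None], _RISK_RGB_A, _RISK_RGB_B)
        image[y: y + h, x: x + w] = block

    return MockSlide(image=image.astype(np.uint8), tissue_mask=tissue,
                     risk_mask=risk_mask)


# ---------------------------------------------------------------------------
# slide cohort with texture-driven survival
# ---------------------------------------------------------------------------

@dataclass
class SlideCohort:
    slides: List[MockSlide]
    records: List[CaseRecord]
    risk_fraction: np.ndarray  # risk-texture share of the tissue area
    base_mag: float = 20.0


def gen_slide_cohort(n_cases: int = 24, slide_px: int = 1280,
                     effect_beta: float = 2.0, censor_rate: float = 0.2,
                     base_mag: float = 20.0, seed: int = 0) -> SlideCohort:
    """Cohort of mock slides whose risk-texture area fraction drives survival.

    Each slide holds one large tissue ellipse with an inscribed risk
    square of per-case varying size; the risk is the z-scored
    risk-to-tissue area fraction times ``effect_beta``.
    """
    rng = np.random.default_rng(seed)
    slides, fracs = [], []
    for i in range(n_cases):
        s_seed = int(rng.integers(0, 2 ** 31))
        size_rng = np.random.default_rng(s_seed + 1)
        half = int(size_rng.uniform(0.08, 0.28) * slide_px)
        slide = gen_mock_slide(slide_px, slide_px, n_tissue_blobs=1,
                               risk_region="auto", seed=s_seed,
                               risk_half_size=max(half, 128),
                               blob_axes=(0.30, 0.42))
        slide.slide_id = f"case_{i:04d}_s0"
        slides.append(slide)
        fracs.append(slide.risk_mask.sum() / max(slide.tissue_mask.sum(), 1))
    fracs = np.asarray(fracs)
    sd = fracs.std()
    risk = effect_beta * (fracs - fracs.mean()) / (sd if sd > 0 else 1.0)
    time, event = _draw_survival(risk, rng, censor_rate=censor_rate)
    ages, sexes = _clinical(rng, n_cases)
    records = [CaseRecord(case_id=f"case_{i:04d}",
                          slide_ids=(slides[i].slide_id,),
                          age=float(ages[i]), sex=str(sexes[i]),
                          os_time=float(time[i]), os_event=int(event[i]))
               for i in range(n_cases)]
    return SlideCohort(slides=slides, records=records, risk_fraction=fracs,
                       base_mag=base_mag)


def slide_cohort_to_bags(cohort: SlideCohort, encoder: PatchEncoder,
                         scale: str = "20x", overlap: float = 0.0,
                         tissue_frac_min: float = 0.5):
    """Run the preprocessing pipeline (segment, tile, encode) on a mock
    cohort.  Returns ``(bags, patch_refs_per_case)`` keyed by case id."""
    bags: Dict[str, Dict[str, FeatureBag]] = {}
    refs_per_case: Dict[str, List[PatchRef]] = {}
    for rec, mock in zip(cohort.records, cohort.slides):
        handle = mock.as_slide(base_mag=cohort.base_mag)
        mask = segment_tissue(handle, downscale=8)
        refs = tile_patches(handle, mask, scale, overlap=overlap,
                            tissue_frac_min=tissue_frac_min)
        if not refs:
            continue
        patches = np.stack([read_patch(handle, r) for r in refs])
        bag = encode_patches(patches, encoder, case_id=rec.case_id,
                             scale=scale, patch_refs=refs)
        bags[rec.case_id] = {scale: bag}
        refs_per_case[rec.case_id] = refs
    return bags, refs_per_case
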