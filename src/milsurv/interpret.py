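"""Attention-based interpretation: percentile-normalized heatmaps and
top-patch extraction.

Raw (pre-softmax) attention logits are rank-normalized per slide into
[0, 1] percentile scores — softmax weights shrink with bag size and are
incomparable across slides, whereas ranks are not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .wsi import PatchRef, SlideHandle

__all__ = [
    "AttentionMap",
    "percentile_normalize",
    "top_patches",
    "render_heatmap",
]


def percentile_normalize(raw_scores) -> np.ndarray:
    """Rank-based percentile scores in [0, 1].

    ``score_i = (rank_i - 1) / (B - 1)`` with average ranks for ties;
    a single instance maps to 1.0.  Monotone: a strictly larger raw
    score never receives a smaller percentile.
    """
    raw = np.asarray(raw_scores, dtype=float).ravel()
    if raw.size < 1:
        raise ValueError("need at least one score")
    if raw.size == 1:
        return np.array([1.0])
    return (rankdata(raw, method="average") - 1.0) / (raw.size - 1.0)


@dataclass
class AttentionMap:
    """Per-patch attention for one slide/scale: raw logits + percentiles."""

    patch_refs: List[PatchRef]
    raw_scores: np.ndarray
    percentile_scores: np.ndarray

    def __post_init__(self) -> None:
        self.raw_scores = np.asarray(self.raw_scores, dtype=float).ravel()
        self.percentile_scores = np.asarray(self.percentile_scores,
                                            dtype=float).ravel()
        n = len(self.patch_refs)
        if not (self.raw_scores.size == self.percentile_scores.size == n):
            raise ValueError("patch_refs and score arrays are not aligned")
        if np.any(self.percentile_scores < 0) or np.any(self.percentile_scores > 1):
            raise ValueError("percentile scores must lie in [0, 1]")

    @classmethod
    def from_logits(cls, patch_refs: Sequence[PatchRef], logits) -> "AttentionMap":
        raw = np.asarray(logits, dtype=float).ravel()
        return cls(list(patch_refs), raw, percentile_normalize(raw))


def top_patches(amap: AttentionMap, k: int = 100) -> List[PatchRef]:
    """The ``k`` highest-attention patches, descending by raw score.

    Ties are broken by row-major patch coordinates (y, then x), so the
    output is fully deterministic.  If the slide holds fewer than ``k``
    patches, all are returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(amap.patch_refs)
    keys = [(-amap.raw_scores[i], amap.patch_refs[i].y, amap.patch_refs[i].x, i)
            for i in range(n)]
    keys.sort()
    if n < k:
        warnings.warn(f"only {n} patches available (< k={k}); returning all",
                      stacklevel=2)
        k = n
    return [amap.patch_refs[i] for *_, i in keys[:k]]


def render_heatmap(slide: Optional[SlideHandle], amap: AttentionMap,
                   downscale: int = 8, colormap: str = "jet",
                   alpha: float = 0.5) -> np.ndarray:
    """Whole-slide attention heatmap as an RGB uint8 array.

    Each patch paints its percentile score over its (downscaled) box;
    overlapping patches — e.g. from 50%-overlap tiling — are averaged
    per pixel.  The heatmap is alpha-blended over the slide thumbnail;
    pixels not covered by any patch keep the plain thumbnail.  Without a
    slide, a white canvas is used (with a warning).
    """
    import math

    from matplotlib import colormaps

    refs = amap.patch_refs
    if not refs:
        raise ValueError("attention map holds no patches")
    if slide is not None:
        thumb = slide.thumbnail(downscale).astype(float) / 255.0
    else:
        warnings.warn("no slide thumbnail available; rendering on white canvas",
                      stacklevel=2)
        W = max(r.x + r.w for r in refs)
        H = max(r.y + r.h for r in refs)
        thumb = np.ones((math.ceil(H / downscale), math.ceil(W / downscale), 3))
    Hc, Wc = thumb.shape[:2]
    acc = np.zeros((Hc, Wc))
    cnt = np.zeros((Hc, Wc))
    for ref, score in zip(refs, amap.percentile_scores):
        x0 = ref.x // downscale
        y0 = ref.y // downscale
        x1 = min(math.ceil((ref.x + ref.w) / downscale), Wc)
        y1 = min(math.ceil((ref.y + ref.h) / downscale), Hc)
        acc[y0:y1, x0:x1] += score
        cnt[y0:y1, x0:x1] += 1.0
    covered = cnt > 0
    vals = np.zeros_like(acc)
    vals[covered] = acc[covered] / cnt[covered]
    cmap = colormaps[colormap]
    colored = cmap(vals)[..., :3]
    out = thumb.copy()
    out[covered] = (1 - alpha) * thumb[covered] + alpha * colored[covered]
    return np.clip(out * 255, 0, 255).astype(np.uint8)
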