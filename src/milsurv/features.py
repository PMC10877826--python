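"""Patch encoding and per-case feature bags.

The MIL model never touches raw pixels: every 256x256 RGB patch is
mapped to a 1024-dimensional embedding by a :class:`PatchEncoder`.  The
encoder is a pluggable contract — a pretrained CNN backbone can be
slotted in, while the test stack uses :class:`MockEncoder`, a
deterministic seeded random projection of per-block image summary
statistics that keeps distinct textures linearly separable.

Bags are persisted in a single HDF5 container with one group per case
and per scale (datasets ``features`` float32 (B, 1024) and ``coords``
int64 (B, 4)), round-tripping bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .wsi import PatchRef, PATCH_SIZE

__all__ = [
    "EMBED_DIM",
    "EncoderError",
    "PatchEncoder",
    "MockEncoder",
    "mock_encoder",
    "FeatureBag",
    "encode_patches",
    "merge_case_bags",
    "FeatureStore",
]

EMBED_DIM = 1024


class EncoderError(RuntimeError):
    """Encoder produced invalid (non-finite) output."""


class PatchEncoder:
    """Contract: map a batch of 256x256 RGB images to (N, 1024) floats."""

    name: str = "base"
    output_dim: int = EMBED_DIM
    deterministic: bool = True

    def encode(self, batch: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, batch: np.ndarray) -> np.ndarray:
        return self.encode(batch)


class MockEncoder(PatchEncoder):
    """Deterministic stand-in encoder for testing the pipeline.

    Per 32x32 block and colour channel it computes mean, variance and
    gradient energy (8x8 blocks x 3 channels x 3 stats = 576 numbers)
    and projects them to 1024 dimensions with a fixed seeded Gaussian
    matrix.  Identical input gives identical output; textures that
    differ in any block statistic map to separable embeddings.
    """

    name = "mock"
    deterministic = True

    _BLOCK = 32

    def __init__(self, seed: int = 0):
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        n_blocks = (PATCH_SIZE // self._BLOCK) ** 2
        self._stat_dim = n_blocks * 3 * 3
        self._proj = rng.normal(0.0, 1.0 / np.sqrt(self._stat_dim),
                                size=(EMBED_DIM, self._stat_dim))

    def _stats(self, batch: np.ndarray) -> np.ndarray:
        n, H, W, C = batch.shape
        b = self._BLOCK
        x = batch.astype(np.float64) / 255.0
        blocks = x.reshape(n, H // b, b, W // b, b, C)
        mean = blocks.mean(axis=(2, 4))
        var = blocks.var(axis=(2, 4))
        gy = np.diff(x, axis=1) ** 2
        gx = np.diff(x, axis=2) ** 2
        # pad gradients back to full size so block reshape works
        gy = np.concatenate([gy, np.zeros((n, 1, W, C))], axis=1)
        gx = np.concatenate([gx, np.zeros((n, H, 1, C))], axis=2)
        grad = (gy + gx).reshape(n, H // b, b, W // b, b, C).mean(axis=(2, 4))
        stats = np.stack([mean, var, grad], axis=-1)  # (n, 8, 8, C, 3)
        return stats.reshape(n, -1)

    def encode(self, batch: np.ndarray) -> np.ndarray:
        batch = np.asarray(batch)
        if batch.ndim == 3:
            batch = batch[None]
        if batch.shape[1:] != (PATCH_SIZE, PATCH_SIZE, 3):
            raise ValueError(
                f"patches must be {PATCH_SIZE}x{PATCH_SIZE} RGB, got {batch.shape[1:]}"
            )
        return (self._stats(batch) @ self._proj.T).astype(np.float32)


def mock_encoder(seed: int = 0) -> MockEncoder:
    """Deterministic test encoder honouring the 1024-d contract."""
    return MockEncoder(seed)


# ---------------------------------------------------------------------------
# feature bags
# ---------------------------------------------------------------------------

@dataclass
class FeatureBag:
    """Per-case, per-scale matrix of instance embeddings.

    ``features`` is a float32 (B, 1024) matrix whose rows are
    index-aligned with ``patch_refs``.
    """

    case_id: str
    scale: str
    features: np.ndarray
    patch_refs: List[PatchRef]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float32)
        if self.features.ndim != 2 or self.features.shape[0] < 1:
            raise ValueError("a bag needs at least one instance (B >= 1)")
        if not np.isfinite(self.features).all():
            raise ValueError("bag features contain non-finite values")
        if len(self.patch_refs) != self.features.shape[0]:
            raise ValueError("patch_refs and feature rows are not aligned")

    @property
    def B(self) -> int:
        return self.features.shape[0]


def encode_patches(patches: Sequence[np.ndarray] | np.ndarray,
                   encoder: PatchEncoder, *, case_id: str = "case",
                   scale: str = "20x",
                   patch_refs: Optional[List[PatchRef]] = None,
                   batch_size: int = 64) -> FeatureBag:
    """Encode patches into a :class:`FeatureBag`.

    Encoding proceeds in mini-batches; results are batch-size invariant
    within 1e-5.  Raises on an empty patch list, wrong patch shape, or
    non-finite encoder output (naming the offending patch).
    """
    batch = np.asarray(patches)
    if batch.ndim == 3:
        batch = batch[None]
    if batch.shape[0] < 1:
        raise ValueError("a bag must contain at least one patch (B >= 1)")
    if batch.shape[1:] != (PATCH_SIZE, PATCH_SIZE, 3):
        raise ValueError(
            f"patches must be {PATCH_SIZE}x{PATCH_SIZE} RGB, got {batch.shape[1:]}"
        )
    if encoder.output_dim != EMBED_DIM:
        raise ValueError(f"encoder output_dim must be {EMBED_DIM}")
    rows = []
    for start in range(0, batch.shape[0], batch_size):
        rows.append(np.asarray(encoder(batch[start: start + batch_size])))
    feats = np.vstack(rows)
    bad = ~np.isfinite(feats).all(axis=1)
    if bad.any():
        raise EncoderError(
            f"encoder {encoder.name!r} produced non-finite output for patch "
            f"index {int(np.flatnonzero(bad)[0])}"
        )
    if patch_refs is None:
        patch_refs = [PatchRef(slide_id=case_id, scale=scale,
                               x=i * PATCH_SIZE, y=0, w=PATCH_SIZE, h=PATCH_SIZE)
                      for i in range(feats.shape[0])]
    return FeatureBag(case_id=case_id, scale=scale, features=feats,
                      patch_refs=list(patch_refs))


def merge_case_bags(bags: Sequence[FeatureBag],
                    scale: Optional[str] = None) -> FeatureBag:
    """Concatenate bags from multiple slides of one case (one scale).

    Instance order is the input order; patch references are preserved.
    """
    if not bags:
        raise ValueError("no bags to merge")
    scale = scale or bags[0].scale
    case_id = bags[0].case_id
    for b in bags:
        if b.case_id != case_id:
            raise ValueError(f"mixed case ids: {b.case_id!r} vs {case_id!r}")
        if b.scale != scale:
            raise ValueError(f"mixed scales: {b.scale!r} vs {scale!r}")
    if len(bags) == 1:
        return bags[0]
    feats = np.vstack([b.features for b in bags])
    refs: List[PatchRef] = []
    for b in bags:
        refs.extend(b.patch_refs)
    return FeatureBag(case_id=case_id, scale=scale, features=feats, patch_refs=refs)


# ---------------------------------------------------------------------------
# on-disk store
# ---------------------------------------------------------------------------

class FeatureStore:
    """HDF5 container of feature bags: groups ``/<case_id>/<scale>``.

    Datasets per group: ``features`` float32 (B, 1024), ``coords`` int64
    (B, 4) = (x, y, w, h) in level-0 pixels, ``slide_ids`` UTF-8 strings.
    """

    def __init__(self, path):
        self.path = str(path)

    def save_bag(self, bag: FeatureBag) -> None:
        import h5py

        with h5py.File(self.path, "a") as f:
            grp = f.require_group(bag.case_id)
            if bag.scale in grp:
                del grp[bag.scale]
            g = grp.create_group(bag.scale)
            g.create_dataset("features", data=bag.features.astype(np.float32))
            coords = np.array([(p.x, p.y, p.w, p.h) for p in bag.patch_refs],
                              dtype=np.int64)
            g.create_dataset("coords", data=coords)
            sids = np.array([p.slide_id for p in bag.patch_refs],
                            dtype=h5py.string_dtype("utf-8"))
            g.create_dataset("slide_ids", data=sids)

    def load_bag(self, case_id: str, scale: str) -> FeatureBag:
        import h5py

        with h5py.File(self.path, "r") as f:
            if case_id not in f or scale not in f[case_id]:
                raise KeyError(f"no bag for case {case_id!r} scale {scale!r}")
            g = f[case_id][scale]
            feats = g["features"][()]
            coords = g["coords"][()]
            sids = [s.decode() if isinstance(s, bytes) else str(s)
                    for s in g["slide_ids"][()]]
        refs = [PatchRef(slide_id=sid, scale=scale, x=int(x), y=int(y),
                         w=int(w), h=int(h))
                for sid, (x, y, w, h) in zip(sids, coords)]
        return FeatureBag(case_id=case_id, scale=scale, features=feats,
                          patch_refs=refs)

    def cases(self) -> List[str]:
        import h5py

        with h5py.File(self.path, "r") as f:
            return sorted(f.keys())

    def scales(self, case_id: str) -> List[str]:
        import h5py

        with h5py.File(self.path, "r") as f:
            return sorted(f[case_id].keys())
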