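"""Training-patch construction from a labeled multi-channel image.

The labeled image is split vertically into a training half and a held-out
half.  The training half is tiled into non-overlapping 48×48 tiles; tiles
whose mean intensity falls below a darkness threshold are discarded, every
remaining tile touching at least one labeled region pixel is kept, and a
seeded random fraction of the remaining tiles is added so the model also
sees unlabeled tissue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MultiplexImage",
    "AtlasLabeledImage",
    "PatchRecord",
    "split_halves",
    "tile_grid",
    "background_filter",
    "build_training_set",
    "DEFAULT_THRESHOLD_FRACTION",
]

DEFAULT_THRESHOLD_FRACTION = 0.02  # of the per-image maximum intensity


@dataclass
class MultiplexImage:
    """Channels-first intensity array with named biomarker channels."""

    data: np.ndarray  # (channels, H, W)
    channel_names: tuple[str, ...] = ()

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected (channels, H, W), got shape {self.data.shape}")
        if self.channel_names and len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match channel count")
        self.channel_names = tuple(self.channel_names)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class AtlasLabeledImage:
    """A multiplex image paired with an integer region mask and name table.

    Mask label 0 is background; labels 1..K index ``region_table``.
    """

    image: MultiplexImage
    mask: np.ndarray  # (H, W) integer labels
    region_table: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.mask = np.asarray(self.mask)
        if self.mask.shape != self.image.data.shape[1:]:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match image plane "
                f"{self.image.data.shape[1:]}"
            )
        if self.mask.min() < 0:
            raise ValueError("mask labels must be non-negative")

    @property
    def region_ids(self) -> tuple[int, ...]:
        return tuple(sorted(self.region_table)) if self.region_table else tuple(
            int(v) for v in np.unique(self.mask) if v != 0
        )


@dataclass(frozen=True)
class PatchRecord:
    """A 48×48 tile addressed by its 0-based top-left pixel (half-open)."""

    row: int
    col: int
    source_half: str = "train"  # train | test
    contains_roi: bool = False


def split_halves(atlas: AtlasLabeledImage) -> tuple[AtlasLabeledImage, AtlasLabeledImage]:
    """Vertical split at floor(W/2); the left half gets the floor width."""
    _, H, W = atlas.image.shape
    if W < 2:
        raise ValueError("image too narrow to split")
    mid = W // 2
    left = AtlasLabeledImage(
        MultiplexImage(atlas.image.data[:, :, :mid], atlas.image.channel_names),
        atlas.mask[:, :mid],
        dict(atlas.region_table),
    )
    right = AtlasLabeledImage(
        MultiplexImage(atlas.image.data[:, :, mid:], atlas.image.channel_names),
        atlas.mask[:, mid:],
        dict(atlas.region_table),
    )
    return left, right


def tile_grid(
    H: int, W: int, tile: int = 48, offset: tuple[int, int] = (0, 0)
) -> list[PatchRecord]:
    """Non-overlapping tiles at (offset + tile·a, offset + tile·b).

    Partial tiles at the right/bottom edges are dropped.
    """
    orow, ocol = offset
    if not (0 <= orow < tile and 0 <= ocol < tile):
        raise ValueError(f"offset components must lie in [0, {tile}), got {offset}")
    records = []
    for r in range(orow, H - tile + 1, tile):
        for c in range(ocol, W - tile + 1, tile):
            records.append(PatchRecord(row=r, col=c))
    return records


def background_filter(tile_intensities: np.ndarray, threshold: float) -> bool:
    """Keep a tile unless its mean intensity is strictly below ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return not (float(np.mean(tile_intensities)) < threshold)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def build_training_set(
    atlas: AtlasLabeledImage,
    region_ids: tuple[int, ...] | None = None,
    other_fraction: float = 0.10,
    threshold: float | None = None,
    seed: int = 0,
    tile: int = 48,
    min_roi_pixels: int = 1,
) -> list[tuple[np.ndarray, np.ndarray, PatchRecord]]:
    """Assemble (image tile, label tile, record) training triples.

    Every non-dark tile overlapping at least ``min_roi_pixels`` labeled
    region pixels is included; a seeded uniform sample (without
    replacement) of ``other_fraction`` of the remaining non-dark tiles is
    added.  ``threshold`` defaults to 2% of the image maximum intensity.
    """
    if not 0.0 <= other_fraction <= 1.0:
        raise ValueError("other_fraction must lie in [0, 1]")
    img = atlas.image.data
    mask = atlas.mask
    _, H, W = img.shape
    if threshold is None:
        threshold = DEFAULT_THRESHOLD_FRACTION * float(img.max())
    if region_ids is None:
        region_ids = atlas.region_ids
    roi_mask = np.isin(mask, np.asarray(region_ids))

    roi_records: list[PatchRecord] = []
    other_records: list[PatchRecord] = []
    for rec in tile_grid(H, W, tile):
        sl = (slice(rec.row, rec.row + tile), slice(rec.col, rec.col + tile))
        if not background_filter(img[:, sl[0], sl[1]], threshold):
            continue
        if int(roi_mask[sl].sum()) >= min_roi_pixels:
            roi_records.append(
                PatchRecord(rec.row, rec.col, source_half="train", contains_roi=True)
            )
        else:
            other_records.append(rec)

    n_other = _round_half_away(other_fraction * len(other_records))
    rng = np.random.default_rng(seed)
    if n_other > 0:
        chosen = rng.choice(len(other_records), size=n_other, replace=False)
        sampled = [other_records[i] for i in sorted(chosen)]
    else:
        sampled = []

    out = []
    for rec in roi_records + sampled:
        sl = (slice(rec.row, rec.row + tile), slice(rec.col, rec.col + tile))
        out.append((img[:, sl[0], sl[1]].copy(), mask[sl].copy(), rec))
    if not out:
        raise ValueError(
            "training set is empty; review the background threshold "
            f"({threshold:g}) against the image intensity range"
        )
    return out
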