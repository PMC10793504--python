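"""Tiled whole-image inference with strided mode-vote smoothing.

Tiling a large image into 48×48 windows produces seams where tiles meet.
The smoother re-runs tiled inference at every offset (m·f, m'·f) for a
stride f dividing 48, then takes the per-pixel statistical mode over the
offset predictions.  With f = 48 there is a single offset and the result
reduces exactly to plain tiling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import SegmenterModel
from .sampling import tile_grid

__all__ = [
    "OffsetPlan",
    "offset_grid",
    "predict_offset_map",
    "mode_smooth",
    "segment_image",
]

TILE = 48


@dataclass(frozen=True)
class OffsetPlan:
    """Stride ``f`` and the (48/f)² pixel offsets it generates."""

    f: int
    offsets: tuple[tuple[int, int], ...]

    @property
    def n(self) -> int:
        return len(self.offsets)


def offset_grid(f: int, tile: int = TILE) -> OffsetPlan:
    """All offsets {m·f : m = 0..(tile/f)−1}² for a stride f dividing tile."""
    if f < 1 or tile % f != 0:
        raise ValueError(f"f must be a positive factor of {tile}, got {f}")
    steps = range(0, tile, f)
    offsets = tuple((r, c) for r in steps for c in steps)
    return OffsetPlan(f=f, offsets=offsets)


def _pad_to_tile(image: np.ndarray, tile: int = TILE) -> tuple[np.ndarray, int, int]:
    """Zero-pad right/bottom to the next tile multiple."""
    _, H, W = image.shape
    Hp = -(-H // tile) * tile
    Wp = -(-W // tile) * tile
    if (Hp, Wp) == (H, W):
        return image, H, W
    out = np.zeros((image.shape[0], Hp, Wp), dtype=image.dtype)
    out[:, :H, :W] = image
    return out, H, W


def predict_offset_map(
    model: SegmenterModel,
    image: np.ndarray,
    offset: tuple[int, int],
    batch_size: int = 64,
) -> tuple[np.ndarray, np.ndarray]:
    """Tiled argmax prediction at one offset.

    Returns (label map, coverage map) over the image plane; pixels in the
    margins not covered by a full tile at this offset carry coverage
    False and label 0.
    """
    image = np.asarray(image)
    if image.ndim != 3:
        raise ValueError(f"expected a (channels, H, W) image, got shape {image.shape}")
    _, H, W = image.shape
    if H < TILE or W < TILE:
        raise ValueError(f"image {H}×{W} smaller than one {TILE}×{TILE} tile")
    records = tile_grid(H, W, TILE, offset)
    labels = np.zeros((H, W), dtype=np.int64)
    covered = np.zeros((H, W), dtype=bool)
    tiles = np.stack(
        [image[:, r.row : r.row + TILE, r.col : r.col + TILE] for r in records]
    ).astype(np.float32)
    pred = model.predict_labels(tiles, batch_size=batch_size)
    for rec, p in zip(records, pred):
        labels[rec.row : rec.row + TILE, rec.col : rec.col + TILE] = p
        covered[rec.row : rec.row + TILE, rec.col : rec.col + TILE] = True
    return labels, covered


def mode_smooth(
    maps: np.ndarray, coverage: np.ndarray, num_classes: int | None = None
) -> np.ndarray:
    """Per-pixel mode over covering label maps; ties go to the smallest label.

    ``maps``: (n_offsets, H, W) int labels; ``coverage``: same-shape bool.
    """
    maps = np.asarray(maps)
    coverage = np.asarray(coverage, dtype=bool)
    if maps.shape != coverage.shape or maps.ndim != 3:
        raise ValueError("maps and coverage must both have shape (n, H, W)")
    if not coverage.any(axis=0).all():
        raise ValueError("every pixel must be covered by at least one offset map")
    if num_classes is None:
        num_classes = int(maps.max()) + 1
    n, H, W = maps.shape
    counts = np.zeros((num_classes, H, W), dtype=np.int32)
    for k in range(n):
        m = maps[k]
        c = coverage[k]
        np.add.at(counts, (m[c], *np.nonzero(c)), 1)
    # argmax scans labels in ascending order: ties break to the smallest index
    return counts.argmax(axis=0).astype(np.int64)


def segment_image(
    model: SegmenterModel,
    image: np.ndarray,
    f: int = 4,
    batch_size: int = 64,
) -> np.ndarray:
    """Mode-smoothed segmentation of a whole multi-channel image.

    The image is zero-padded to a 48-multiple for inference and the
    output cropped back; offset (0, 0) guarantees full coverage.
    """
    image = np.asarray(image)
    if image.ndim != 3:
        raise ValueError(f"expected a (channels, H, W) image, got shape {image.shape}")
    plan = offset_grid(f)
    padded, H, W = _pad_to_tile(image)
    maps, cov = [], []
    for off in plan.offsets:
        m, c = predict_offset_map(model, padded, off, batch_size=batch_size)
        maps.append(m)
        cov.append(c)
    smoothed = mode_smooth(
        np.stack(maps), np.stack(cov), num_classes=model.config.num_classes
    )
    return smoothed[:H, :W]
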