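"""Synthetic multiplex tissue phantoms for end-to-end testing.

A phantom emulates the structure of a multiplex immunofluorescence section:
a bright tissue area on a dark background, containing several anatomical
regions, each with its own per-channel intensity signature and cell-like
speckle texture.  Regions come in three visibility classes mirroring how
real regions present to an annotator:

1. plainly visible — strong mean-intensity contrast in some channels;
2. texture-defined — weak mean contrast, but clearly different speckle
   statistics (cell density) in some channels;
3. cryptic — first-order statistics matched to the surrounding tissue,
   differing only in higher-order texture (speckle correlation length).

With ``mirror=True`` (default) the left half is reflected onto the right,
emulating the approximate bilateral symmetry that justifies training on
one half of a section and testing on the other.  No claim of anatomical
or optical realism is made: blobs are thresholded smoothed noise and no
microscope effects (bleed-through, stitching, vignetting) are simulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .sampling import AtlasLabeledImage, MultiplexImage
from .training import Click, ClickSet

__all__ = ["RegionSpec", "PhantomConfig", "generate_phantom", "generate_clickset"]

CLICK_BUDGET = 30  # typical upper bound of an interactive fine-tuning round


@dataclass(frozen=True)
class RegionSpec:
    """One synthetic region: area, shape wiggliness, channel signature."""

    name: str
    target_area: int
    signature: tuple[float, ...]  # per-channel additive offsets
    visibility_class: int = 1  # 1 plainly visible, 2 texture-defined, 3 cryptic
    shape_complexity: float = 0.6  # 0 = round blob, 1 = very wiggly
    speckle_density_factor: float = 1.0  # class-2 texture contrast
    speckle_sigma: float | None = None  # class-3 correlation length override

    def __post_init__(self):
        if self.visibility_class not in (1, 2, 3):
            raise ValueError("visibility_class must be 1, 2 or 3")
        if self.target_area <= 0:
            raise ValueError("target_area must be positive")


def _default_regions(channels: int) -> tuple[RegionSpec, ...]:
    def sig(**kv):
        v = np.zeros(channels)
        for ch, val in kv.items():
            v[int(ch[1:])] = val
        return tuple(v)

    return (
        RegionSpec("plain", 3600, sig(c0=0.35, c1=0.25), visibility_class=1),
        RegionSpec(
            "textured",
            3600,
            sig(c2=0.10, c3=0.08),
            visibility_class=2,
            speckle_density_factor=3.0,
        ),
        RegionSpec(
            "cryptic",
            3600,
            sig(),
            visibility_class=3,
            speckle_sigma=2.5,
        ),
    )


@dataclass
class PhantomConfig:
    """Canvas geometry, region roster and noise levels of a phantom."""

    height: int = 480
    width: int = 480
    channels: int = 8
    regions: tuple[RegionSpec, ...] | None = None
    background_level: float = 0.005  # below the default sampling threshold
    tissue_level: float = 0.30
    margin: int = 48  # dark frame; its tiles fail the background filter
    speckle_density: float = 0.01  # cell-like dots per pixel
    speckle_amplitude: float = 0.25
    speckle_sigma: float = 1.0
    noise_scale: float = 0.02  # additive Gaussian
    contrast_margin: float = 0.15  # guaranteed class-1 inside/outside contrast
    mirror: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.height % 48 or self.width % 48:
            raise ValueError("height and width must be multiples of 48")
        if self.regions is None:
            self.regions = _default_regions(self.channels)
        self.regions = tuple(self.regions)
        for r in self.regions:
            if len(r.signature) != self.channels:
                raise ValueError(
                    f"region {r.name!r} signature length {len(r.signature)} "
                    f"!= channels {self.channels}"
                )


def _blob_mask(
    rng: np.random.Generator,
    H: int,
    W: int,
    center: tuple[float, float],
    area: int,
    complexity: float,
    allowed: np.ndarray,
) -> np.ndarray:
    """Top-``area`` pixels of (noise − radial bowl), restricted to ``allowed``."""
    yy, xx = np.mgrid[0:H, 0:W]
    radius = np.sqrt(area / np.pi)
    dist = np.hypot(yy - center[0], xx - center[1]) / radius
    noise = gaussian_filter(rng.standard_normal((H, W)), sigma=max(radius / 3.0, 2.0))
    noise /= np.abs(noise).max() + 1e-12
    score = -dist + 1.6 * complexity * noise
    score[~allowed] = -np.inf
    flat = score.ravel()
    k = min(area, int(allowed.sum()))
    thresh = np.partition(flat, -k)[-k]
    return (score >= thresh) & allowed


def _speckle(
    rng: np.random.Generator,
    shape: tuple[int, int],
    density: float,
    amplitude: float,
    sigma: float,
) -> np.ndarray:
    dots = (rng.random(shape) < density).astype(np.float64) * amplitude
    return gaussian_filter(dots, sigma=sigma)


def generate_phantom(cfg: PhantomConfig) -> AtlasLabeledImage:
    """Deterministic phantom: (channels, H, W) image + integer region mask."""
    rng = np.random.default_rng(cfg.seed)
    H, W, C = cfg.height, cfg.width, cfg.channels
    m = cfg.margin
    tissue = np.zeros((H, W), dtype=bool)
    tissue[m : H - m, m : W - m] = True

    half_w = W // 2
    mask = np.zeros((H, W), dtype=np.int64)
    place_w = half_w if cfg.mirror else W
    interior = tissue.copy()
    interior[:, place_w:] = False
    # keep blobs clear of the mirror seam so reflected copies stay disjoint
    interior[:, max(place_w - 8, 0) : place_w] = False

    usable_h = H - 2 * m
    centers = []
    nreg = len(cfg.regions)
    for i in range(nreg):
        cy = m + (i + 0.5) * usable_h / nreg
        cx = m + 0.45 * (place_w - 2 * m) + (0.25 * (place_w - 2 * m) if i % 2 else 0)
        centers.append((cy, cx))

    for rid, (spec, center) in enumerate(zip(cfg.regions, centers), start=1):
        allowed = interior & (mask == 0)
        blob = _blob_mask(rng, H, W, center, spec.target_area, spec.shape_complexity, allowed)
        realized = int(blob.sum())
        if realized < 0.5 * spec.target_area:
            raise ValueError(
                f"region {spec.name!r} does not fit the canvas "
                f"(placed {realized} of {spec.target_area} pixels)"
            )
        mask[blob] = rid

    if cfg.mirror:
        mirrored = mask[:, :half_w][:, ::-1]
        mask[:, W - half_w :] = np.maximum(mask[:, W - half_w :], mirrored)

    image = np.full((C, H, W), cfg.background_level, dtype=np.float64)
    base_speckle = np.stack(
        [
            _speckle(rng, (H, W), cfg.speckle_density, cfg.speckle_amplitude, cfg.speckle_sigma)
            for _ in range(C)
        ]
    )
    for c in range(C):
        plane = np.full((H, W), cfg.tissue_level)
        plane += base_speckle[c]
        image[c][tissue] = plane[tissue]

    for rid, spec in enumerate(cfg.regions, start=1):
        inside = mask == rid
        for c in range(C):
            image[c][inside] += spec.signature[c]
        if spec.speckle_density_factor != 1.0:
            # texture-defined: denser, dimmer dots keep the mean comparable
            for c in range(C):
                alt = _speckle(
                    rng,
                    (H, W),
                    cfg.speckle_density * spec.speckle_density_factor,
                    cfg.speckle_amplitude / spec.speckle_density_factor,
                    cfg.speckle_sigma,
                )
                image[c][inside] += alt[inside] - base_speckle[c][inside]
        if spec.speckle_sigma is not None:
            # cryptic: same dot density, different correlation length,
            # first-order statistics matched to the surrounding tissue
            for c in range(C):
                alt = _speckle(
                    rng, (H, W), cfg.speckle_density, cfg.speckle_amplitude, spec.speckle_sigma
                )
                ref = base_speckle[c]
                alt = (alt - alt.mean()) / (alt.std() + 1e-12) * ref.std() + ref.mean()
                image[c][inside] += alt[inside] - ref[inside]

    image += rng.normal(0.0, cfg.noise_scale, size=image.shape)
    np.clip(image, 0.0, None, out=image)

    table = {rid: spec.name for rid, spec in enumerate(cfg.regions, start=1)}
    return AtlasLabeledImage(
        MultiplexImage(image.astype(np.float32), tuple(f"ch{c}" for c in range(C))),
        mask,
        table,
    )


def _window_sums(binary: np.ndarray, tile: int) -> np.ndarray:
    """Sum of ``binary`` over every tile×tile window (summed-area table)."""
    sat = np.zeros((binary.shape[0] + 1, binary.shape[1] + 1), dtype=np.int64)
    sat[1:, 1:] = np.cumsum(np.cumsum(binary.astype(np.int64), axis=0), axis=1)
    return (
        sat[tile:, tile:]
        - sat[:-tile, tile:]
        - sat[tile:, :-tile]
        + sat[:-tile, :-tile]
    )


def generate_clickset(
    mask: np.ndarray,
    region_id: int,
    n_pos: int,
    n_neg: int,
    seed: int = 0,
    *,
    region_name: str | None = None,
    tile: int = 48,
    min_inside: float = 0.9,
    neg_margin: int = 96,
) -> ClickSet:
    """Seeded synthetic expert clicks for one region.

    Positive patches have ≥ ``min_inside`` of their extent inside the
    region; negative patches are fully outside it, preferentially drawn
    from the region's surroundings (within ``neg_margin`` pixels of its
    bounding box).  Exceeding the ~30-patch interactive budget only emits
    a warning.
    """
    mask = np.asarray(mask)
    inside = mask == region_id
    if not inside.any():
        raise ValueError(f"region {region_id} not present in the mask")
    if n_pos + n_neg > CLICK_BUDGET:
        warnings.warn(
            f"{n_pos + n_neg} clicks exceed the ~{CLICK_BUDGET}-patch budget "
            "typical of an interactive round",
            stacklevel=2,
        )
    sums = _window_sums(inside, tile)
    pos_ok = np.argwhere(sums >= min_inside * tile * tile)
    neg_ok_mask = sums == 0
    rows, cols = np.nonzero(inside)
    r0, r1 = rows.min(), rows.max()
    c0, c1 = cols.min(), cols.max()
    near = np.zeros_like(neg_ok_mask)
    nr0 = max(r0 - neg_margin - tile, 0)
    nc0 = max(c0 - neg_margin - tile, 0)
    near[nr0 : r1 + neg_margin + 1, nc0 : c1 + neg_margin + 1] = True
    neg_near = np.argwhere(neg_ok_mask & near)
    neg_any = np.argwhere(neg_ok_mask)
    if len(pos_ok) < n_pos:
        raise ValueError(
            f"only {len(pos_ok)} candidate positive patches for region {region_id}, "
            f"requested {n_pos}"
        )
    if len(neg_any) < n_neg:
        raise ValueError(f"only {len(neg_any)} candidate negative patches, requested {n_neg}")
    rng = np.random.default_rng(seed)
    pos_idx = rng.choice(len(pos_ok), size=n_pos, replace=False)
    neg_pool = neg_near if len(neg_near) >= n_neg else neg_any
    neg_idx = rng.choice(len(neg_pool), size=n_neg, replace=False)
    entries = [Click(int(r), int(c), "region") for r, c in pos_ok[pos_idx]]
    entries += [Click(int(r), int(c), "background") for r, c in neg_pool[neg_idx]]
    name = region_name if region_name is not None else str(region_id)
    return ClickSet(region=name, entries=tuple(entries), round_index=1)
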