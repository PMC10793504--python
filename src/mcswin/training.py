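"""Multi-class pre-training and click-driven binary fine-tuning.

The workflow mirrors interactive region refinement: a multi-class network
is pre-trained on the global segmentation task, then for each region of
interest a two-class copy is seeded from the learned weights (output head
re-initialised) and fine-tuned on a handful of expert-chosen 48×48
patches ("clicks"), each labelled wholly as region or background.  Click
sets are edited between rounds — patches added or removed — and training
resumes from the current weights.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from .config import ModelConfig
from .model import SegmenterModel, build_model
from .nn.tensor import Tensor, cross_entropy

__all__ = [
    "TrainConfig",
    "Click",
    "ClickSet",
    "fit_tiles",
    "pretrain_multiclass",
    "init_binary_from_multiclass",
    "finetune_binary",
    "incremental_round",
]

MAX_FINETUNE_EPOCHS = 400  # interactive rounds stay within this budget


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings for pre-training and fine-tuning."""

    epochs: int = 100
    lr: float = 1e-4
    batch_size: int = 32
    seed: int = 0
    weight_decay: float = 0.0
    loss: str = "cross_entropy"
    optimizer: str = "adamw"

    def __post_init__(self):
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")
        if self.loss != "cross_entropy":
            raise ValueError(f"unsupported loss: {self.loss}")
        if self.optimizer != "adamw":
            raise ValueError(f"unsupported optimizer: {self.optimizer}")


# ---------------------------------------------------------------------------
# click bookkeeping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Click:
    """Top-left corner of a 48×48 patch labelled region or background."""

    row: int
    col: int
    label: str  # "region" | "background"

    def __post_init__(self):
        if self.label not in ("region", "background"):
            raise ValueError(f"label must be 'region' or 'background', got {self.label!r}")

    @property
    def location(self) -> tuple[int, int]:
        return (self.row, self.col)


@dataclass(frozen=True)
class ClickSet:
    """The effective click set for one region, with per-round provenance."""

    region: str
    entries: tuple[Click, ...] = ()
    round_index: int = 1
    history: tuple[dict, ...] = ()  # one {"round", "added", "removed"} per edit round

    def __post_init__(self):
        locs = [c.location for c in self.entries]
        if len(locs) != len(set(locs)):
            raise ValueError("duplicate click locations in the effective set")

    def __len__(self) -> int:
        return len(self.entries)

    def edited(
        self,
        additions: tuple[Click, ...] = (),
        removals: tuple[tuple[int, int], ...] = (),
    ) -> "ClickSet":
        """Next-round set: (current ∪ additions) \\ removals."""
        current = {c.location: c for c in self.entries}
        for loc in removals:
            if tuple(loc) not in current:
                raise ValueError(f"cannot remove non-existent click at {loc}")
            del current[tuple(loc)]
        for c in additions:
            if c.location in current:
                raise ValueError(f"duplicate click at {c.location}")
            current[c.location] = c
        record = {
            "round": self.round_index + 1,
            "added": [c.location for c in additions],
            "removed": [tuple(loc) for loc in removals],
        }
        return ClickSet(
            region=self.region,
            entries=tuple(current.values()),
            round_index=self.round_index + 1,
            history=self.history + (record,),
        )

    # -- JSON lines interchange ------------------------------------------
    def to_jsonl(self) -> str:
        lines = [
            json.dumps(
                {
                    "region": self.region,
                    "row": c.row,
                    "col": c.col,
                    "label": c.label,
                    "round": self.round_index,
                }
            )
            for c in self.entries
        ]
        return "\n".join(lines) + ("\n" if lines else "")

    @classmethod
    def from_jsonl(cls, text: str, region: str | None = None) -> "ClickSet":
        entries = []
        rounds = [1]
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            d = json.loads(line)
            if region is not None and d["region"] != region:
                continue
            entries.append(Click(int(d["row"]), int(d["col"]), d["label"]))
            rounds.append(int(d.get("round", 1)))
            region_seen = d["region"]
        if not entries:
            raise ValueError("no clicks found" + (f" for region {region!r}" if region else ""))
        return cls(region=region or region_seen, entries=tuple(entries), round_index=max(rounds))


# ---------------------------------------------------------------------------
# optimisation
# ---------------------------------------------------------------------------


def fit_tiles(
    model: SegmenterModel,
    tiles: np.ndarray,
    labels: np.ndarray,
    cfg: TrainConfig,
) -> list[float]:
    """Train ``model`` in place on (N, C, S, S) tiles with (N, S, S) labels.

    Returns the per-epoch mean cross-entropy.  Deterministic for a fixed
    seed: shuffling uses its own generator and numpy kernels are exact.
    """
    tiles = np.ascontiguousarray(tiles, dtype=np.float32)
    labels = np.ascontiguousarray(labels, dtype=np.int64)
    if tiles.ndim != 4 or labels.ndim != 3 or tiles.shape[0] != labels.shape[0]:
        raise ValueError("expected tiles (N, C, S, S) and labels (N, S, S)")
    K = model.config.num_classes
    if labels.max() >= K:
        raise ValueError(f"label {labels.max()} out of range for {K} classes")
    present = np.unique(labels)
    missing = sorted(set(range(K)) - set(int(v) for v in present))
    if missing:
        warnings.warn(
            f"classes {missing} absent from the training labels; "
            "they cannot be predicted (potential DNP)",
            stacklevel=2,
        )
    rng = np.random.default_rng(cfg.seed)
    opt = nn.AdamW(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    n = tiles.shape[0]
    history: list[float] = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            logits = model(tiles[idx])  # (B, K, S, S)
            flat = logits.transpose(0, 2, 3, 1).reshape(-1, K)
            loss = cross_entropy(flat, labels[idx].reshape(-1))
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
    return history


def pretrain_multiclass(
    model: SegmenterModel,
    training_set: list[tuple[np.ndarray, np.ndarray, object]] | tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig,
) -> tuple[SegmenterModel, list[float]]:
    """Pre-train on the global multi-class task; returns (model, loss history)."""
    if isinstance(training_set, tuple) and len(training_set) == 2:
        tiles, labels = training_set
    else:
        if not training_set:
            raise ValueError("training set is empty")
        tiles = np.stack([t[0] for t in training_set])
        labels = np.stack([t[1] for t in training_set])
    history = fit_tiles(model, tiles, labels, cfg)
    return model, history


def init_binary_from_multiclass(
    model: SegmenterModel,
    *,
    seed: int = 0,
    head_init: str = "random",
    region_id: int | None = None,
) -> SegmenterModel:
    """Two-class copy of a multi-class model, output head re-initialised.

    Every non-head parameter is copied exactly.  ``head_init='random'``
    draws a fresh small-variance head; ``'copy'`` reuses the multi-class
    head columns for background (class 0) and ``region_id``.
    """
    cfg = model.config
    d = cfg.to_dict()
    d["num_classes"] = 2
    binary = build_model(ModelConfig.from_dict(d), seed=seed)
    state = model.state_dict()
    head_keys = [k for k in state if k.startswith("head.")]
    for k in head_keys:
        del state[k]
    bstate = binary.state_dict()
    for k in head_keys:
        if head_init == "copy":
            if region_id is None:
                raise ValueError("head_init='copy' requires region_id")
            src = model.state_dict()[k]  # (C, K)
            bstate[k] = np.stack([src[:, 0], src[:, region_id]], axis=1)
        # 'random': keep the freshly seeded initialisation
        state[k] = bstate[k]
    binary.load_state_dict(state)
    return binary


def _click_tiles(
    clicks: ClickSet, image: np.ndarray, tile: int = 48
) -> tuple[np.ndarray, np.ndarray]:
    image = np.asarray(image)
    _, H, W = image.shape
    xs, ys = [], []
    for c in clicks.entries:
        if not (0 <= c.row <= H - tile and 0 <= c.col <= W - tile):
            raise ValueError(f"click at {c.location} falls outside the image")
        xs.append(image[:, c.row : c.row + tile, c.col : c.col + tile])
        ys.append(np.full((tile, tile), 1 if c.label == "region" else 0, dtype=np.int64))
    return np.stack(xs).astype(np.float32), np.stack(ys)


def finetune_binary(
    model: SegmenterModel,
    clicks: ClickSet,
    image: np.ndarray,
    cfg: TrainConfig,
    *,
    max_epochs: int = MAX_FINETUNE_EPOCHS,
) -> tuple[SegmenterModel, list[float]]:
    """Fine-tune a binary model on whole-patch click labels.

    Targets are uniform per-pixel labels over each clicked patch.  The
    epoch budget is capped at ``max_epochs`` (default 400).
    """
    if model.config.num_classes != 2:
        raise ValueError("finetune_binary expects a two-class model")
    if len(clicks) == 0:
        raise ValueError("click set is empty")
    if cfg.epochs > max_epochs:
        raise ValueError(
            f"fine-tuning budget exceeded: {cfg.epochs} epochs > {max_epochs}"
        )
    labels_present = {c.label for c in clicks.entries}
    if len(labels_present) == 1:
        warnings.warn(
            f"all clicks are labelled {labels_present.pop()!r}; "
            "fine-tuning will collapse toward that class",
            stacklevel=2,
        )
    tiles, labels = _click_tiles(clicks, image)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # single-label sets already warned above
        history = fit_tiles(model, tiles, labels, cfg)
    return model, history


def incremental_round(
    model: SegmenterModel,
    clicks: ClickSet,
    additions: tuple[Click, ...],
    removals: tuple[tuple[int, int], ...],
    image: np.ndarray,
    cfg: TrainConfig,
) -> tuple[SegmenterModel, ClickSet, list[float]]:
    """One edit-and-resume round of incremental fine-tuning.

    The click set becomes (previous ∪ additions) \\ removals and training
    resumes from the passed model's current parameters.
    """
    updated = clicks.edited(tuple(additions), tuple(removals))
    model, history = finetune_binary(model, updated, image, cfg)
    return model, updated, history
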