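# mcswin

Semantic segmentation of highly multiplexed immunofluorescence (IF)
microscopy imagery with a multi-channel shifted-window transformer and
human-in-the-loop incremental fine-tuning.

Multiplex IF images carry tens of biomarker channels over a single tissue
section; anatomical regions (e.g. corpus callosum, habenular nuclei) are
defined by the joint cell-patterning statistics of those channels. Expert
annotation is scarce, so a single "global" multi-class segmentation is
usually sub-optimal region by region. This package implements a workflow
for that setting:

1. **Multi-channel Swin encoder–decoder.** A U-shaped transformer for
   48×48 multi-channel tiles. A depthwise separable 4×4/stride-4 patch
   embedding gives each biomarker channel its own 12 learned filters (no
   cross-channel mixing at the input), yielding a latent depth
   C = 12 × n_channels (96 at 8 channels) on a 12×12 token grid. Windowed
   multi-head self-attention (window 6) alternates with shifted windows
   (shift 3, wrap-masked) in paired blocks; 2×2 patch merging halves the
   grid and doubles the depth, patch expansion inverts it, and exactly two
   skip connections fuse encoder features into the decoder. The deepest
   scale is a 3×3 grid — inside a single window — so the bottleneck holds
   one attention block. The frozen reference configuration
   (`reference_config()`) has exactly **4,990,032** trainable parameters,
   about a quarter of the 20M-parameter 224×224 original it adapts.
2. **Incremental fine-tuning.** After pre-training the multi-class model
   on labelled tiles from one half of a section, each region is refined as
   a binary problem: a two-class model is *seeded* from the multi-class
   weights (output head re-initialised), then fine-tuned on a handful of
   expert "clicks" — 48×48 patches labelled wholly as region or
   background (≤30, often <10). Click sets can be edited (patches added or
   removed) between rounds, resuming from the current weights.
3. **Strided mode-vote inference.** Whole images are segmented tile by
   tile at every offset (m·f, m′·f) for a stride f dividing 48, giving
   n = (48/f)² overlapping label maps; the output is the per-pixel
   statistical mode (ties → smallest label). f = 48 reduces exactly to
   plain tiling.
4. **Evaluation.** Per-region intersection-over-union
   IoU = |A∩B| / |A∪B|, with multi-class maps binarised per region (all
   other regions count as background) and never-predicted regions flagged
   DNP and counted as 0 in means.

The network and its training loop run on a small numpy reverse-mode
autodiff backend (`mcswin.nn`) — no GPU or deep-learning framework is
required — so the whole workflow is testable end-to-end on a CPU with the
synthetic phantoms in `mcswin.phantom`.

## Worked example

A synthetic 480×480 eight-channel phantom contains three regions, one per
visibility class: `plain` (clear intensity contrast), `textured` (cell
density differs, mean barely does) and `cryptic` (only the speckle
correlation length differs). Train the global model on the left half,
then refine each region on the held-out right half from 30 clicks:

```python
import numpy as np
from mcswin import (
    PhantomConfig, generate_phantom, generate_clickset, split_halves,
    build_training_set, compact_config, MulticlassSegmenter,
    BinaryRegionSegmenter, iou,
)

atlas = generate_phantom(PhantomConfig(seed=1))          # 480x480, 8 channels
left, right = split_halves(atlas)                        # train on the left half
tiles = build_training_set(left, seed=1)
X = np.stack([t[0] for t in tiles]); y = np.stack([t[1] for t in tiles])

est = MulticlassSegmenter(config=compact_config(num_classes=4),
                          epochs=100, lr=2e-3, batch_size=8, seed=1).fit(X, y)
multi = est.segment(right.image.data, f=48)              # held-out right half

for rid, name in right.region_table.items():
    base, dnp = iou(multi == rid, right.mask == rid)
    base = 0.0 if dnp else base
    clicks = generate_clickset(right.mask, rid, 10, 20, seed=1 + rid, region_name=name)
    fine = BinaryRegionSegmenter(base_model=est, epochs=200, lr=1e-3,
                                 batch_size=8, seed=1 + rid)
    fine.fit_clicks(clicks, right.image.data)
    refined = fine.segment(right.image.data, f=48)
    value, dnp = iou(refined == 1, right.mask == rid)
    print(f"{name:9s} multiclass IoU {base:.2f} -> fine-tuned IoU {0.0 if dnp else value:.2f}")
```

Output:

```
plain     multiclass IoU 0.95 -> fine-tuned IoU 0.41
textured  multiclass IoU 0.00 -> fine-tuned IoU 0.71
cryptic   multiclass IoU 0.00 -> fine-tuned IoU 0.05
```

The pattern mirrors what incremental refinement is for: a region the
global model already segments nearly perfectly gains nothing from 30
clicks, while regions the global model misses entirely are recovered —
dramatically where texture carries signal, marginally where almost
nothing does. Two of the three regions improve strictly over the
binarised multi-class baseline.

A `mcswin` command-line tool wraps the same steps
(`phantom`, `sample`, `pretrain`, `seed-binary`, `finetune`, `segment`,
`evaluate`); see `mcswin --help`.

## Layout

- `src/mcswin/nn/` — numpy autodiff backend (tensors, layers, AdamW)
- `src/mcswin/model.py` — architecture primitives and the assembled network
- `src/mcswin/config.py` + `reference_config.yaml` — frozen configuration
- `src/mcswin/sampling.py` — half-split, tiling, darkness filter, patch sets
- `src/mcswin/training.py` — pre-training, binary seeding, click fine-tuning
- `src/mcswin/inference.py` — offset plans, mode-vote smoothing
- `src/mcswin/metrics.py` — IoU, DNP, per-region reports
- `src/mcswin/phantom.py` — synthetic multiplex phantoms and click sets
- `src/mcswin/estimators.py` — sklearn-style wrappers
- `docs/methods.md` — modelling assumptions, parameters, limitations
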