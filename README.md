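# dranet

Binary segmentation of stained-tissue (histology-style) images with a
**dynamic regional attention network**: a group-normalized ResNet-style
encoder–decoder whose convolutional stream is augmented by two attention
mechanisms —

- an **ordered shift MLP** block, which ranks feature channels by pooled
  importance, groups them, and displaces the groups a few pixels along the
  height and then the width axis (zero-filled) so per-position MLPs mix
  neighbouring locations; and
- a **dynamic regional attention (DRA)** gate, which collapses the feature
  map to one channel, partitions it into `k` non-overlapping regions of
  mutually similar pixels using the similarity measure
  `S = sqrt((d_f/m)² + (d_s/s)²)` (feature proximity `d_f`, spatial
  proximity `d_s`, `s = sqrt(H·W/k)`), replaces each pixel by its region
  mean, and applies a sigmoid to form a spatial attention gate.

Training minimizes `L = 0.5·L_BCE + L_Dice` on the probability map, and
evaluation reports IoU, Dice, recall, specificity and precision (in %) from
pixel confusion counts, with `Dice = 2·IoU/(1+IoU)`.

The package targets users who want to study these two mechanisms — region
partitioning modes, channel-shift geometry, parameter/FLOP budgets — on CPU
without GPU infrastructure: the network runs on a small numpy autodiff core
shipped in `dranet.nn`, and a synthetic stained-tissue generator makes
every stage (training included) testable without downloading datasets.
Directory trees of real data (e.g. the public gland-segmentation
benchmarks) are supported through the same `images/`, `masks/`, split-list
layout.

## Worked example

Generate a small synthetic dataset, train the full model briefly, and
evaluate:

```sh
dranet make-synthetic ds --preset easy --n-train 16 --n-test 4 --size 96 --seed 5

cat > cfg.yaml <<'YAML'
model:
  stage_widths: [16, 16, 32, 64, 128]
  decoder_widths: [32, 24, 16, 16]
  input_size: [96, 96]
  dra: {k: 5}
train:
  epochs: 8
  input_size: 96
  seed: 0
YAML

dranet train ds run --config cfg.yaml
dranet evaluate run/checkpoint.npz ds
```

The train command prints the best held-out Dice and final loss:

```json
{"best": {"dice": 0.9310872262888378, "epoch": 7},
 "final_loss": 0.3778275290017919}
```

and evaluation on the 4 test images prints the five aggregate percentages
(per-image averaged):

```json
{"iou": 89.99, "dice": 94.70, "recall": 96.04,
 "specificity": 98.51, "precision": 93.78}
```

i.e. after 8 epochs on 16 images the model already overlaps ~90% (IoU) of
the ground-truth foreground. Longer runs (30 epochs, 64 images) reach Dice
≈ 99 on this preset.

At the full 224×224 configuration, `dranet profile` reproduces the model's
parameter budget for the four ablation variants:

```
variant         params (M)    GFLOPs
conv                 14.32      4.36
conv+mlp             15.27      4.40
conv+dra             14.33      4.37
conv+mlp+dra         15.28      4.40
```

Other commands: `predict` (segment one image), `sweep-k` (train one model
per region count k and tabulate metrics), `visualize-regions` (write a
region-partition overlay PNG with receptive-field boxes), `make-synthetic`
presets `easy | hard | glas_like | cocahis_like`.

## Library surface

```python
import dranet

cfg = dranet.ModelConfig()                    # 224x224, both blocks, k=5
model = dranet.assemble(cfg, seed=0)
prob = model(image)                           # (H, W) in (0, 1)

part = dranet.partition_regions(projected, dranet.DRAConfig(k=5, mode="local"))
gate = dranet.fuse_regions(projected, part)   # piecewise-constant region means

dranet.count_parameters(model)                # ProfileReport, millions + breakdown
dranet.evaluate_metrics(prob.data, mask)      # IoU/Dice/recall/specificity/precision
```

See `docs/methods.md` for the model's assumptions, parameter conventions,
numerical choices and known limitations.

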