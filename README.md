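# stomadetect

Automated detection and counting of stomata — the microscopic pores on
the leaf surface that control gas exchange — in light-microscope images
of epidermal leaf impressions. Stomatal density (stomata per mm² of leaf
area) is a core functional trait in plant ecology and land-surface
modeling, and counting stomata by eye through a microscope is the slow
step in acquiring it. This package implements the complete
leaf-impression-to-coordinates workflow for researchers who want
reproducible, automated counts from calibrated micrographs.

## The method

Detection is cast as classification of fixed-size windows:

1. **Patching** — the micrograph is divided into overlapping
   120 × 120 px windows by a sliding window (stride 30 px). A window is
   labeled *positive* only if a stoma is fully visible inside it.
2. **Classification** — a CNN scores each window with a two-way softmax,
   (absence, presence) ∈ [0, 1]². Three architectures are provided:
   a shallow net (conv 8–16–32, dense 2 × 32; 180,242 parameters), a
   deeper one (conv 32–64–128, dense 2 × 1024; 23,297,090), and a VGG19
   variant with a frozen convolutional base (47,297,602 total,
   27,273,218 trainable). Training uses Adam, dropout and
   rotation/flip augmentation; a seeded NumPy backend makes runs
   exactly reproducible on CPU.
3. **Clustering** — window centers with confidence ≥ τ (default 0.7) are
   merged by flat-kernel mean shift (bandwidth 60 px); each mode is one
   detected stoma with coordinate, confidence and cluster size.
4. **Density** — counts are converted to stomata/mm² via the microscope
   calibration (default view field 344 × 258 µm at 1,600 × 1,200 px).
5. **Evaluation** — detections are matched one-to-one to ground truth
   within 60 px; precision = TP/(TP+FP), recall = TP/(TP+FN), and
   F = 2PR/(P+R) are swept over the 19-point threshold grid
   0.05…0.95; count agreement is summarized as
   100·(1 − |computed − manual|/manual) and by OLS regression of
   computed on manual counts.

A seeded synthetic micrograph generator (textured epidermis, elliptical
stomata with dark pore and light guard-cell rim, hair/bubble/smudge
artifacts) provides exact ground truth so the entire pipeline is testable
without microscope data. See `docs/methods.md` for the model details and
design decisions.

## Worked example

```python
from stomadetect import (SynthConfig, generate_dataset, PatchConfig,
                         build_training_set, PatchCNNClassifier,
                         DetectionConfig, detect_stomata, match_detections,
                         precision_recall_f)

train = generate_dataset(2, SynthConfig.easy(seed=1, image_id="train"))
test = generate_dataset(1, SynthConfig.easy(seed=2, image_id="test"))

ds = build_training_set([s.pair for s in train], PatchConfig(), seed=1)
clf = PatchCNNClassifier(architecture="basic_shallow", epochs=8,
                         random_state=1).fit(ds.X, ds.y)

scene = test[0]
dets = detect_stomata(clf, scene.micrograph, PatchConfig(), DetectionConfig())
mr = match_detections(dets, scene.annotations, radius_px=60)
p, r, f, _ = precision_recall_f(mr.tp, mr.fp, mr.fn)
print(f"{len(dets)} detections vs {len(scene.annotations)} stomata; "
      f"P={p:.2f} R={r:.2f} F={f:.2f}")
print(scene.micrograph.density(len(dets)))
```

Output (a few minutes on one CPU):

```
23 detections vs 25 stomata; P=1.00 R=0.92 F=0.96
DensityResult(image_id='test_000', count=23, area_mm2=0.088752, density_per_mm2=259.1490895979809)
```

After only 8 epochs on two training images the detector finds 23 of the
25 stomata with no false positives (precision 1.0, recall 0.92); the
density line converts the count through the 0.0888 mm² calibrated view
field. With the full desk-scale recipe (5 training scenes, 30 epochs)
the held-out F-score at τ = 0.7 is ≈ 0.95–0.99.

The same pipeline is scriptable from the shell:

```bash
stomadetect simulate --n-images 3 --seed 1 --out-dir imgs
stomadetect patchify --images imgs --truth imgs/annotations.csv --out patches.npz
stomadetect train --patches patches.npz --arch basic_shallow --epochs 30 --out w.npz
stomadetect detect --weights w.npz --images imgs --threshold 0.7 --out dets.csv
stomadetect evaluate --detections dets.csv --truth imgs/annotations.csv
stomadetect density --detections dets.csv
```

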