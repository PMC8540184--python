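# discseg

Two-stage cascade segmentation of three specific intervertebral discs
(one isolated upper disc, two adjacent lower discs) from 2D sagittal
spine images, together with an instance-aware evaluation protocol and a
synthetic phantom generator that stands in for restricted clinical data.

## Method

Segmenting *specific* discs is harder than segmenting all of them: a
single network tends to also fire on the look-alike neighbouring discs,
producing redundant or misplaced instances. The cascade addresses this:

1. **Stage 1** — a MultiRes encoder-decoder is trained on windows cropped
   around the lower two discs. At inference it runs on the full image and
   only the two bottom-most connected components are retained.
2. **Distance features** — exact Euclidean distance transforms of the two
   retained discs are normalized and stacked with the raw image into a
   3-channel input.
3. **Stage 2** — a second network segments the upper disc from that fused
   input; only the top-most component is kept.
4. The instances are merged into a labeled mask (1 = upper disc from
   stage 2; 2, 3 = lower discs from stage 1, top to bottom). Predictions
   that cannot form the required instances are flagged as failed, never
   repaired.

Evaluation declares an image correct when the predicted instance count
equals 3 and every disc's coverage `C_ik = |R∩S|/|S|` is ≥ 0.70;
accuracy is the fraction of correct images and the mean IoU averages the
binary-foreground Jaccard index over *all* test images.

The networks are implemented on a small numpy reverse-mode autodiff
engine (no GPU framework required): MultiRes blocks with 1/6–1/3–1/2
branch splits, Res-path skip connections, batchnorm, focal loss, Adam.

## Layout

- `src/discseg/phantom.py` — synthetic spine phantoms + dataset manifests
- `src/discseg/instance_ops.py` — connected components, top-to-bottom
  relabeling, lower-disc cropping
- `src/discseg/distance_features.py` — Euclidean distance maps, channel fusion
- `src/discseg/network/` — autodiff engine, MultiRes U-shaped network,
  focal loss, training loop
- `src/discseg/pipeline.py` — two-stage training/inference orchestration,
  single-stage baseline, experiment runner
- `src/discseg/evaluation.py` — IoU, discrimination criterion, accuracy,
  sample-size utility
- `src/discseg/cli.py`, `src/discseg/fileio.py` — command line + PNG/BMP I/O

## CLI

```sh
discseg generate --n 50 --seed 1 --size 64 --out data/
discseg train-stage1 --manifest data/manifest.csv --model-out stage1.npz --epochs 40
discseg train-stage2 --manifest data/manifest.csv --model-out stage2.npz --epochs 40
discseg predict --image data/img_00000.png \
    --stage1-model stage1.npz --stage2-model stage2.npz --out preds/
discseg evaluate --pred-dir preds/ --ref-manifest data/manifest.csv
discseg experiment --train-manifest data/manifest.csv \
    --test-manifest test/manifest.csv --seed 7 --single-stage --out runs/exp1
```

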