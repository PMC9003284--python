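# focusfield

Defocus-blur segmentation for partially blurred (low depth-of-field)
images, built from two cooperating pieces:

1. **Ternary-pattern sharpness map** — every pixel is coded by comparing
   its P circular neighbors against it with a dead-zone threshold; the
   resulting upper/lower binary patterns are labeled with the uniform
   rotation-invariant scheme, and the windowed frequency of
   sharp-indicative labels (high-count uniform bins + the non-uniform
   bin), averaged over the upper and lower maps, gives a per-pixel
   sharpness score in [0, 1]. Pixels below an adaptive threshold
   (2 × map mean) are classified blurred and zeroed.
2. **Pulse-coupled neural network** — one neuron per pixel with feeding
   input F, 3×3 linking L, internal activity U = F(1 + δL), and an
   exponentially decaying dynamic threshold. The decay factor, linking
   strength, judgment criterion and threshold floor are estimated
   adaptively from gray-level statistics of low/mid/high local-variation
   pixel populations. Synchronously firing waves are labeled into
   connected components; wave boundaries accumulate into an edge map
   that is thresholded, closed and hole-filled into the final in-focus
   mask.

Companion modules provide the full evaluation-metric suite (precision,
recall, accuracy, weighted F-measure, MCC, weighted Jaccard, Dice,
specificity), an EDAS-style multi-criteria ranker that reproduces a
published 10-method worked example, and a seeded synthetic-fixture
generator (partially blurred disks/rings/blobs with ground-truth masks,
plus microscopy-like presets) so everything is testable offline.

## CLI

```bash
# segment the in-focus region of an image
focusfield segment photo.png -o out/ --window 33 --ternary-threshold 0.02

# compare a predicted mask against ground truth (JSON report)
focusfield eval out/photo_mask.png gt.png

# rank a decision matrix (default: the packaged 10-method benchmark)
focusfield rank                       # as-printed sign convention
focusfield rank matrix.csv --weights 0.6125,0.2737,0.1139 --standard-edas

# generate synthetic fixtures with ground truth
focusfield fixtures --kind disk --seed 0 -n 10 --size 256 -o fixtures/
```

`focusfield segment` accepts a YAML config mirroring `PipelineConfig`
(`descriptor:` block for neighbors/radius/threshold/window, plus
`median_window`, `ltp_threshold`, `edge_threshold`, `pcnn_overrides`).

## Library

```python
import focusfield as ff

img, gt = ff.fixtures.make_partial_blur(ff.fixtures.FixtureSpec(seed=7))
result = ff.segment(img)            # SegmentationResult with intermediates
report = ff.evaluate(result, gt)    # metrics in both polarity conventions

matrix = ff.edas.load_benchmark_matrix()
ranking = ff.edas.rank(matrix)      # full EDAS table stack
```

Note on the ranker: the packaged worked example was computed with a
distance sign convention opposite to textbook EDAS (below-average values
score "positive" on beneficial criteria). `focusfield rank` reproduces
that convention by default; pass `--standard-edas` (or
`convention="standard"`) for the textbook orientation.

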