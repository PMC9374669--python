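# polycap

A pure-NumPy re-implementation of the onboard intelligence of an
AI-empowered wireless capsule endoscope for colorectal polyp screening:

- **`polycap.net`** — a ~3.2M-parameter, 15-layer depthwise-separable grid
  detector (240×240×3 → 4×4×15), built from a validated architecture
  description with exact parameter and INT8-footprint accounting.  Forward
  *and* backward passes are implemented in NumPy, so no deep-learning
  framework is required.
- **`polycap.head`** — decoding of the 4×4 grid into 48 proposal boxes,
  confidence filtering (score ≥ threshold, default 0.65) and greedy
  non-maximum suppression.
- **`polycap.train`** — the dataset protocol (class balancing, tenfold
  augmentation with polyp-preserving crops, patient-wise 80/10/10 split)
  and an Adam training loop with a YOLO-style composite loss.
- **`polycap.evaluate`** — greedy detection matching and average precision
  (AP_n at IoU n/100, all-point interpolation, pooled ranking).
- **`polycap.synth`** — a seeded generator of endoscopy-like frames
  (mucosa texture, vessels, elliptical polyps with tight ground-truth
  boxes, cleanliness debris, WLI/NBI renderings, per-patient style).
  Explicitly artificial; it exists because the clinical trial data is
  private.
- **`polycap.sim`** — a capsule-session simulator: adaptive 1→2 fps frame
  rate, delete-or-transmit policy (every 5th insignificant frame kept for
  localization), WLI→NBI follow-up captures, over-the-air network
  replacement, and a two-point-calibrated power model yielding operating
  time versus sparsity.
- **`polycap.cli`** — `polycap generate|train|eval|detect|simulate`.

## CLI quick start

```sh
polycap generate data/demo --seed 0                 # synthetic dataset + annotations
polycap train data/demo ckpt.npz --epochs 10        # train a compact detector
polycap eval data/demo ckpt.npz report.json         # AP_25 / AP_50 report
polycap detect data/demo ckpt.npz dets.json         # per-frame boxes
polycap simulate data/demo ckpt.npz session.csv     # capsule session log
```

Datasets are a directory of PNG/BMP frames plus one versioned
`annotations.json` (boxes as 0-based upper-left `(x, y, w, h)`) and a
`manifest.json` recording seed and config hash. The canonical full-size
architecture ships as `src/polycap/configs/canonical.yaml`.

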