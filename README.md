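# smarttrace

Self-learning neuron reconstruction from 3D light-microscopy volumes.

Automatic neuron tracers fail in characteristic ways: signal dropout creates
gaps that stop component-based tracers cold, intensity inhomogeneity causes
over- or under-tracing, and the right parameters differ from image to image.
`smarttrace` implements a self-supervised framework (SmartTracing) that
improves an existing tracer's reconstruction *without any human-provided
training labels*: the training data come from the reconstruction itself.

## How it works

Given a volume `I` and an initial reconstruction (from any tracer, supplied
as SWC, or from the built-in baseline tracer):

1. **Confidence scoring.** The reconstruction is decomposed into segments at
   branch points. For each segment `L_ij` between endpoints `i` and `j`, the
   image is masked to 0 along the segment's tube, and the cheapest
   intensity-weighted path `L*_ij` from `i` to `j` is found in the masked
   image (masked voxels are impassable, as a front marching at speed
   proportional to intensity cannot cross zero intensity). With arc-length
   weighted means taken on the original image,

   ```
   Ī_ij  = ∫_L I(x) dx / |L|,        C_ij = Ī*_ij / Ī_ij .
   ```

   `C ≪ 1` means the detour had to cross dark background — no alternative
   pathway exists and the segment is reliable. `C ≈ 1` means a genuine
   alternative corridor exists (a loop, a parallel neurite) and the segment
   is uncertain. Segments with `C ≤ θ` (default 0.5) become exemplars.
   For inverted-contrast (brightfield) volumes, scoring runs on `I_max − I`.

2. **Exemplar layers.** Three shells around the confident centerlines label
   the volume: core layer → foreground samples, middle annulus → uncertain,
   outer annulus → background samples; neighborhoods of uncertain segments
   are uncertain too. Balanced foreground/background voxel samples are drawn
   uniformly.

3. **Features and selection.** Each sample voxel is described by the full
   3-level separable 3D wavelet decomposition (Haar by default) of the
   16×16×16 window around it — 4096 coefficients, exactly the window's voxel
   count. The 20 most characterizing coefficients are selected by
   minimum-redundancy maximum-relevance (mRMR), greedily maximizing
   `I(c, f) − (1/|S|) Σ_{s∈S} I(f, s)` over mutual informations of 3-state
   discretized features.

4. **Classification and growth.** A soft-margin RBF-kernel SVM (C = 1,
   γ = 1/|S|) is trained on the standardized selected features. The
   predicted neuron foreground is grown by front propagation: foreground
   samples are pre-labeled, the front marches to adjacent unknown voxels,
   and each is classified exactly once.

5. **Re-tracing.** Background voxels are zeroed; foreground voxels dimmer
   than the tracing threshold (1) are raised to it; the tracer runs again on
   the adjusted image. Because the learned foreground bridges signal gaps,
   the final reconstruction recovers structure the initial trace missed.

The loop can run iteratively: a partially recovered gap contributes training
exemplars in the next round, which can finish crossing a gap that one round
cannot (`run_iterative`).

## Worked example

Generate a 96×128×128 phantom — a radius-2 neurite at intensity 200 on
background 10 with Gaussian noise (σ = 5) and a 4-voxel signal gap that cuts
off 40 % of the structure — then run one self-learning round:

```bash
python - <<'EOF'
from smarttrace.phantoms import PhantomSpec, straight_tube_polyline
spec = PhantomSpec(shape=(96,128,128), branches=[straight_tube_polyline((96,128,128))],
                   noise_sigma=5.0, gaps=[(0, 0.6, 4)])
open("gap_spec.json", "w").write(spec.to_json())
EOF
smarttrace phantom --spec gap_spec.json --out-image gap.tif --out-swc gap_gt.swc
echo '{"tracer": {"soma_seed": [48, 64, 12]}}' > cfg.json
smarttrace run --image gap.tif --config cfg.json --seed 1 --out final.swc --report report.json
```

The report (abridged) reads:

```json
{
  "initial": {"total_length": 66.0,  "n_branches": 1, "n_tips": 1},
  "final":   {"total_length": 113.1, "n_branches": 1, "n_tips": 1},
  "improvement_ratio": 1.71,
  "confident_fraction": 1.0,
  "n_samples_per_class": 500
}
```

The ground truth is 111 voxels long. The initial trace stops at the gap
(66 voxels, 59 % of the truth); the gap voxels are classified foreground by
the self-trained SVM, the adjusted image reconnects the two halves, and the
final trace recovers the full neurite (113 voxels; ratio 1.71 ≥ 1.2, the
conventional bar for a significantly improved reconstruction).

Every stage is also available on its own: `smarttrace score` writes
per-segment confidence scores (and a per-node score sidecar for
confidence-colored rendering), `smarttrace measure` computes the standard
morphology summary (total length, bifurcations, branches, tips), and
`smarttrace trace-baseline` runs the built-in shortest-path-tree tracer.
External tracers plug in via `--initial-swc`.

## Scope

The package targets single-neuron volumes with bright (or, via the
brightfield flag, dark) tubular signal. The built-in tracer is a deliberately
minimal stand-in for a production tracer — gap-limited by construction, so
that gap recovery is attributable to the learning loop, not the tracer. See
`docs/methods.md` for the model details, parameter defaults, and known
limitations.
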