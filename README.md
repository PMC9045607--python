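# filmbend

Analytics for chemo-mechanically bending sensor films: from video frames of a
hanging filament to calibration models between vapor composition and bending.

## The problem

Thin polyaniline–cellulose-acetate (PANI-CA) films bend when exposed to
volatile organic compounds — notably acetone, a skin-emitted biomarker of
metabolic state. A strip of film suspended in the headspace above an
acetone/ethanol/water mixture deflects over tens of seconds; the *speed* of
the response, more than its amplitude, carries the composition signal, and a
slow water-driven drift of the resting angle makes the film's state
history-dependent. Quantifying this requires (1) tracking the filament's
midline and tip angle in every video frame, (2) checking that the shape
ensemble is low-dimensional enough for simple summaries, (3) fitting each
exposure transient, and (4) regressing between composition and response.
`filmbend` implements that pipeline, plus a synthetic experiment generator
with frame-level ground truth so the whole chain is testable without the
original videos.

## What is inside

| module | contents |
| --- | --- |
| `filmbend.synthetic` | solution table, randomized-block exposure designs, hysteretic three-mode bending simulator, constant-curvature frame renderer, manual-click emulation |
| `filmbend.tracking` | row-scan midline tracker (Otsu binarization, per-row means with exact two-means splitting for curled filaments, root→tip path assembly), tip angle via PCA of the distal quarter, manual-vs-auto comparison |
| `filmbend.shape` | arc-length resampling, pooled shape PCA, cumulative variance, reconstruction |
| `filmbend.transients` | triple-exponential fits θ(t) = a₀ + Σᵢ aᵢ·exp(−λᵢt) by variable projection with multi-start, time-to-95%-deflection, Δ tip angle |
| `filmbend.calibration` | forward model (composition → Δ tip angle), per-analyte inverse models (fit parameters → fractions) with feature ablation, R² = squared Pearson correlation, hysteresis diagnostics |
| `filmbend.pipeline` / `filmbend.cli` | end-to-end orchestration, CSV/JSON formats, `filmbend` command with `design`, `simulate`, `render`, `track`, `fit`, `shapes`, `calibrate`, `run` subcommands |

The core transient model, in the field's standard notation:

    ϑ(t) = a₀ + a₁e^(−λ₁t) + a₂e^(−λ₂t) + a₃e^(−λ₃t),   0 < λ₁ ≤ λ₂ ≤ λ₃

fit to each trial's tip-angle transient; the seven parameters then serve as
features for the inverse calibration. See `docs/methods.md` for the full model
descriptions, parameter defaults and numerical choices.

## Worked example

Run a small synthetic session — two randomized blocks over the six solutions,
60 s exposures rendered and tracked at 5 Hz — and inspect the results:

```python
from filmbend import SessionConfig, run_session
from filmbend.synthetic import GeneratorParams
from filmbend.shape import cumulative_variance

config = SessionConfig(
    seed=7,
    n_blocks=2,              # 12 trials
    exposure_s=60.0,
    params=GeneratorParams(frame_rate=5.0),
    out_dir="results/demo",
)
result = run_session(config)

modes = result.shape_modes
print(f"trials tracked : {result.trials.shape[0]}")
print(f"frames tracked : {result.tracked.n_frames}")
print(f"PC1+PC2 variance: {100 * cumulative_variance(modes, 2):.2f}%")
print(f"inverse R^2     : {result.models['inverse_full']['r2_per_target']}")
print(f"forward R^2     : {result.models['forward']['r2_per_target']}")
print(f"hysteresis lag-1: {result.models['hysteresis']['lag1_autocorrelation']:.3f}")
```

Output:

```
trials tracked : 12
frames tracked : 3600
PC1+PC2 variance: 99.99%
inverse R^2     : {'f_acetone': 0.9586062096411728, 'f_ethanol': 0.7179458289096645}
forward R^2     : {'delta_theta_deg': 0.8011270401536046}
hysteresis lag-1: 0.216
```

Reading the numbers: the tracked shape ensemble is essentially
one-dimensional (two principal components explain 99.99% of the shape
variance — the filament mostly reorients as a rigid-ish arc); the inverse
model recovers the acetone fraction from the transient-fit features much
better than the ethanol fraction (0.96 vs 0.72 in-sample R², the acetone
dominance built into the response-rate structure); and the per-trial initial
angles are positively autocorrelated (0.216), the fingerprint of the slow
water-driven baseline drift. `results/demo/` now holds `angles.csv`,
`trials.csv`, `shape_modes.json`, `models.json` and `run.log`, each stamped
with the seed and a config hash; rerunning with the same seed reproduces them
byte-for-byte. On real films these R² values are substantially lower (≈0.45
acetone / ≈0.30 ethanol reported for films of this type); the synthetic
stand-in validates the pipeline, not real-world sensing performance.

The same run from the shell:

```bash
filmbend run --seed 7 --out results/demo
filmbend track --frames my_frames/ --frame-rate 30 --out results/real   # video mode
```

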