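# pcnnseg

Unsupervised segmentation of grayscale biological and medical images with
pulse-coupled neural networks (PCNNs), including a variable-step-size model
whose segmentation granularity is controlled by a sinusoidal step schedule
with a single supervised parameter.

## The model

A PCNN places one leaky-integrator neuron on every pixel. Each neuron
accumulates the stimulus `S` (the normalized pixel intensity) and pulses
from its 8-neighborhood into an internal activity `U`, and emits a binary
pulse `Y = 1` whenever `U` strictly exceeds a dynamic threshold `E`. The
threshold decays exponentially and jumps by `VE` after each pulse, so it
sweeps downward through the intensity range and peels off one intensity
stratum per iteration; laterally coupled neurons with similar stimuli pulse
in the same iteration ("synchronous firing"). The per-pixel iteration of
the first informative pulse — the **firing map** — is the segmentation:
pixels sharing a first-fire time form one group.

Four variants are implemented:

- **pcnn** — the classic feeding/linking neuron
  (`L[n] = e^{-aL}L[n-1] + VL ΣWY`, `F[n] = e^{-aF}F[n-1] + S + VF ΣMY`,
  `U = F(1+βL)`);
- **spcnn** — the simplified PCNN,
  `U[n] = S(1 + βVL ΣWY[n-1]) + e^{-aF}U[n-1]`,
  `E[n] = e^{-aE}E[n-1] + VE Y[n-1]`, with all parameters set automatically
  from image statistics: `aF = log(1/σ)`, `VL = 1`, `β = (Smax/S')/(6VL)`,
  `VE = e^{-aF} + 1 + 6βVL`,
  `aE = log(VE / (Smax(1-e^{-3aF})/(1-e^{-aF}) + 6βVL e^{-aF}))`,
  where `σ` is the population std of the normalized image, `Smax` its
  maximum and `S'` its Otsu threshold;
- **fixedstep** — the same recurrence run at a fixed non-integer step size
  `ST ∈ (0,1]`, which scales both decay clocks to `e^{-aF·ST}`,
  `e^{-aE·ST}`;
- **varstep** — the second-order recurrence in which ST may change every
  iteration,

  ```
  U[n] = SβVL(ΣWY[n-1] − ΣWY[n-2]) + (1+e^{-aF·ST})U[n-1] − e^{-aF·ST}U[n-2]
  ```

  driven by the bounded sinusoidal schedule
  `ST(t) = 0.5·sin(w·t + φ) + 0.5` with `w = log(1/σ)`. With `ST ≡ 1` this
  reduces exactly to the SPCNN. Small steps slow the threshold sweep and
  split the image into more groups; large steps strengthen synchronization
  and merge them — so the schedule makes the number of segmentation groups
  controllable.

The phase `φ ∈ [0, π/w]` is the only supervised parameter: it is tuned by
maximizing the IoU between the model's binarized output and manual masks
(`tuning.optimize_phi`), and transfers to unseen images with similar gray
statistics. Binary segmentation places a threshold in the gray gap between
the two most populous firing groups. Evaluation metrics: IoU, Dice, TPR,
TNR and pixelwise cross-entropy.

A synthetic phantom generator (`pcnnseg.phantoms`) produces
piecewise-constant multi-gray-level images with pixel-exact ground-truth
masks, so the whole pipeline is testable without any image downloads.

## Worked example

```
$ pcnnseg synth --out phantom --seed 0          # four-band phantom + masks
$ pcnnseg segment phantom/phantom.png --model spcnn --out seg
4 groups -> seg
$ pcnnseg evaluate --pred seg/mask.png --truth phantom/mask_3.png
{
  "iou": 1.0,
  "dice": 1.0,
  "tpr": 1.0,
  "tnr": 1.0,
  "cross_entropy": 1.000000500029089e-06
}
```

The phantom has four bands at intensities 0.1 / 0.2 / 0.4 / 0.8. The
automatic parameters derived from it are `aF = 1.3164`, `aE = 0.7095`,
`VE = 3.2710`, `β = 0.3338` (from `σ = 0.2681`, `Smax = 0.80`,
`S' = 0.3994`); the threshold sweep makes the four bands fire at iterations
4, 5, 6 and 7, giving four groups whose masks equal the ground-truth bands
exactly, and the binarization threshold lands at 0.60 — the midpoint of
the gray gap between the two largest groups — so the recovered foreground
mask matches the brightest band with IoU = Dice = 1. The same run from
Python:

```python
from pcnnseg import four_level_phantom, segment_image

ph = four_level_phantom(seed=0)
res, fmap = segment_image(ph.image, model="spcnn")
print(res.n_groups, res.group_fire_times)   # -> 4 [4, 5, 6, 7]
```

`pcnnseg tune` optimizes φ against annotated masks and writes a config that
`pcnnseg segment --config` replays bit-identically; `pcnnseg render` writes
the false-color firing map (earlier-firing neurons get cooler colors, blue
through red).

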