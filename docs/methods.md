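# Methods

This note records the model equations as implemented, the numerical and
design choices that were genuinely open, what the synthetic phantoms do and
do not emulate, and the known limitations.

## Lattice dynamics

All four variants share the pulse generator `Y[n] = 1 iff U[n] > E[n]`
(strict inequality; ties do not fire) and double-precision arithmetic.
Pulse coupling is the 3×3 convolution `ΣW·Y` with the kernel
`[[0.5,1,0.5],[1,0,1],[0.5,1,0.5]]` and zero padding (out-of-lattice
neighbors never fired). The kernel's total weight is 6, which is the
constant baked into the automatic parameter formulas (`6βVL`), so those
formulas presuppose exactly this kernel; both kernels are replaceable but
the automatic setting is only calibrated for the default.

**Classic PCNN.** The textbook feeding/linking neuron. The feeding input
includes the stimulus additively, `F[n] = e^{-aF}F[n-1] + S + VF ΣMY[n-1]`:
without the stimulus term a zero-initialized lattice receives no input and
can never fire, contradicting the defining behavior of the model (a
constantly driven neuron settles into periodic firing). The threshold
update compares against the decayed threshold and then bumps with the
current pulse: `E[n] = e^{-aE}E[n-1] + VE·Y[n]`.

**SPCNN.** `U[n] = S(1 + βVL ΣWY[n-1]) + e^{-aF}U[n-1]`;
`E[n] = e^{-aE}E[n-1] + VE·Y[n-1]`, i.e. the threshold seen by the pulse
at iteration n already contains the undecayed bump from the previous
pulse. This bookkeeping is what the automatic parameter derivation
presupposes: from the zero state every neuron fires at n = 1, at n = 2 the
threshold equals `VE` and the identity `U[2] = VE·S ≤ VE` guarantees
silence, and from n = 3 the threshold sweep `VE·e^{-aE(n-2)}` peels off
intensity strata.

**Variable step.** The second-order recurrence

    U[n] = SβVL(ΣWY[n-1] − ΣWY[n-2]) + (1+q)U[n-1] − q·U[n-2],  q = e^{-aF·ST}

with the threshold clock sharing the step, `E[n] = e^{-aE·ST}E[n-1] +
VE·Y[n-1]`. The first iteration runs the first-order bootstrap
`U[1] = S(1+βVL ΣWY[0]) + q·U[0]`. For constant ST the recurrence is
algebraically equivalent to first-order iteration with scaled decay (it is
derived from it by eliminating S), and at ST = 1 it reproduces the SPCNN;
both reductions are verified to ≤ 1e-10 over 100 iterations in the test
suite, and error growth is benign because the homogeneous roots of the
recurrence are 1 and q ≤ 1.

**Initialization.** All models start from the zero state (`F = L = U = E =
Y = 0`) so that the four variants are comparable from identical initial
conditions; an optional stimulus preload (`u0="stimulus"`) sets `U[0] = S`
instead, which perturbs only the first bootstrap step and changes no
firing decision from the zero state. With the zero threshold every
stimulated neuron pulses at iteration 1; this synchronous calibration
flash carries no contrast information, so firing maps are recorded from
iteration 2 (`record_from=2`, configurable).

## Automatic parameters and the step schedule

From the normalized image: `σ` (population std), `Smax` (maximum), and
`S'` — a reference intensity separating object from background, for which
no closed definition exists in the method; the Otsu threshold is used, as
in the lineage the parameter formulas come from, and it is exposed as an
override. Then `aF = log(1/σ)` (natural logs throughout, consistent with
the `e^{-aF}` decays), `VL = 1`, `β = (Smax/S')/6`, `VE = e^{-aF} + 1 +
6βVL`, and `aE = log(VE/(Smax(1-e^{-3aF})/(1-e^{-aF}) + 6βVL·e^{-aF}))`.
`aE > 0` holds exactly when `6β(1-e^{-aF}) > e^{-2aF}`; since intensities
live in [0,1], the attainable σ is at most 0.5 and the inequality always
holds (6β = Smax/S' ≥ 1). For hypothetical σ > ~0.6 with small `Smax/S'`
the printed formula turns negative and `spcnn_auto_params` raises rather
than emit a non-decaying threshold.

The schedule is `ST(t) = 0.5 sin(wt + φ) + 0.5` with `w = log(1/σ)` and
`φ ∈ [0, π/w]` (closed interval). The scheduler floors emitted steps at
1e-12: a step of exactly 0 would freeze both decay clocks, and the floor
is far below any fidelity tolerance, so the logged sequence still equals
the closed form to 1e-12. Step sizes are valid on (0, 1].

## Segmentation readout

Groups are the equivalence classes of the first-pulse iteration, ordered by
fire time. Each pixel contributes only its first pulse, so the periodic
re-firing that follows (the refractory interval of the brightest stratum,
roughly `log(VE/U)/aE ≈ 2–3` iterations, is shorter than the full sweep to
the darkest stratum) cannot merge classes. An optional strict mode
(`first_cycle_only=True`) truncates groups at the earliest second pulse
found anywhere on the lattice and merges later first-firers into the final
group; it is not the default because on phantoms spanning a wide intensity
range the darkest stratum legitimately first-fires after the brightest has
re-fired.

Binarization takes the two most populous groups (ties favor the earlier),
reads each group's gray range [min, max] from the stimulus, and thresholds
at the midpoint of the gap between the ranges; when the ranges overlap
(noisy images) it falls back to the midpoint of the two group medians and
flags the fallback in the run log. Foreground is the brighter side by
default (`polarity="dark"` flips it). The false-color rendering maps
ascending fire time onto blue → light blue → green → yellow → orange →
red, with never-fired pixels black.

## Phantoms: what they emulate and what they do not

Phantoms are piecewise-constant images (bands, non-overlapping disks on a
background, or Voronoi "blobs") with exact masks and no anti-aliasing, so
region statistics are known in closed form and IoU targets are crisp.
Noise is additive zero-mean Gaussian on the normalized scale, clipped to
[0, 1] — the model consumes normalized stimuli, so noise levels are quoted
on that scale.

The canonical four-level phantom uses monotone bands at 0.1/0.2/0.4/0.8.
The design rule: the threshold decays by `e^{-aE}` per iteration, so
consecutive gray levels occupy consecutive distinct firing iterations
exactly when their ratio lies in `(e^{-2aE}, e^{-aE})` (≈ (0.24, 0.49) for
these statistics); with geometric ratio 1/2 each stratum fires one
iteration after the next brighter one. In a monotone band layout every
region touches only adjacent levels, so the one-iteration coupling boost a
freshly fired band gives its darker neighbor lands exactly on that
neighbor's own firing iteration — which is why the recovered group masks
are pixel-exact. When a dark region borders a much brighter one (disks on
a dark background, or level ratios below `e^{-2aE}`), the boost fires a
one-pixel rim an iteration early and the rim forms its own thin group:
this is the synchronous-firing edge capture inherent to the model, not an
artifact, and the test suite asserts it for a 0.2/0.8 band pair.

Phantoms do not emulate texture, gradients, microscope PSFs, or
anti-aliased boundaries; passing tests show the mechanics of threshold
sweep, coupling and tuning are right, not that the method segments natural
images at any particular accuracy.

## Supervised tuning and the experiment harnesses

`optimize_phi` evaluates a uniform grid (default 64 candidates, optionally
extended by seeded random refinement) of φ over [0, π/w], scoring each by
mean IoU of the binarized output over the training pairs; ties go to the
smaller φ, failures (e.g. a single firing group) score 0 and are logged.
The tuning IoU uses the binarized whole mask by default; a best-group mode
(max IoU over per-group masks) is available, since either reading is
defensible for multi-part outputs. Cross-entropy clamps hard predictions
to [1e-6, 1-1e-6] because the model emits binary pulses, not
probabilities.

`random_st_search` draws fully random per-iteration step sequences
(uniform on [0, 1]) and keeps the best-of-n and a top-k list; it
upper-bounds any fixed schedule up to sampling noise and is the baseline
the sinusoidal schedule is meant to replace cheaply.

`noise_experiment` scores each model's binarized output on noisy phantom
replicates against the clean truth (default: the brightest stratum), and
summarizes Dice retention `Dice(σ_hi)/Dice(σ_lo)`. φ for the variable-step
model is tuned per noise level on a training replicate drawn at the same
noise level with a seed disjoint from the evaluation seeds, matching the
supervised workflow in which training and deployment images come from the
same population (on a clean piecewise-constant phantom the IoU surface
over φ is flat at 1.0 and tuning would degenerate to the tie-break).

Measured on the canonical band phantom (σ = 0.1 → 0.2, 5 seeds): the
variable-step model's Dice goes 0.97 → 0.77 (retention ≈ 79%) while the
SPCNN's goes 0.63 → 0.78 (retention ≈ 123%). The SPCNN "retention above
100%" is a ratio artifact of a degenerate baseline: at σ = 0.1 its two
most populous firing groups are adjacent bins inside the dark smear, the
fallback threshold lands near 0.27, and Dice starts low — added noise can
only move it up. The variable-step model dominates in absolute Dice at
σ = 0.1 and matches at σ = 0.2; a retention-ratio comparison between the
two models is only meaningful when both baselines are sane, which on
equal-area synthetic strata the SPCNN's is not. The harness reports both
the absolute Dice cells and the ratios so this failure mode is visible.

## Problem sizes and determinism

Default `Nmax = 100` iterations. Tests and the acceptance script use
32×32 random stimuli for the trajectory equivalences (20 stimuli × 100
iterations), 64×64–96×96 phantoms for segmentation and tuning, a 64-point
φ grid, and 5 evaluation seeds for the noise harness — sizes at which
every property is exercised at interactive speed. All randomness flows
through explicit integer seeds (`numpy.random.default_rng`); re-running
any segmentation with identical inputs is bit-identical, and run configs
serialize to JSON with a stable content hash.

## Known limitations

- The automatic parameters assume the default kernel (total weight 6) and
  8-bit-style normalized intensities; exotic kernels need hand-set
  parameters.
- The linear-interpolation reading of non-integer steps (fractional array
  indexing) is intentionally not implemented; fixed decimal steps are
  served by the recurrence form, which supersedes it.
- No continuous-time integration of the underlying ODE; the discrete
  recurrences are the model.
- Cross-entropy on hard binary predictions is a clamped surrogate, useful
  for ranking, not a calibrated likelihood.
- φ tuning requires annotated masks; no unsupervised adaptation or
  frame-to-frame φ propagation for video is provided.
- The training/test "cosine similarity" screening mentioned alongside the
  tuning workflow has no defined representation and is not implemented;
  gray-statistics similarity (σ, hence w) is the operative notion here.
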