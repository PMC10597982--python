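# Methods

This note documents the models, numerical choices and design decisions
behind `petkin`. It is written for a reader who wants to know exactly what
the package computes and what its tests do and do not demonstrate.

## The kinetic model

Tracer kinetics follow the two-tissue compartment model (2TCM). With plasma
input `C0(t)` and rate constants `K1, k2, k3, k4` (all 1/min; `K1` in
ml/min/ml, treated numerically as 1/min), the nondisplaceable concentration
`C1` and the specific (bound) concentration `C2` obey

    dC1/dt = K1 C0(t) - (k2 + k3) C1 + k4 C2
    dC2/dt = k3 C1 - k4 C2

The tissue curve is `CT = C1 + C2` and has the closed form

    CT(t) = a * C0 ⊗ exp(-α1 t) + b * C0 ⊗ exp(-α2 t)

where `α1,2 = (s ∓ sqrt(s² - 4 k2 k4))/2` with `s = k2+k3+k4`, and
`a = K1(k3+k4-α1)/(α2-α1)`, `b = K1 - a`. The eigenvalues satisfy Vieta's
identities `α1+α2 = s`, `α1·α2 = k2·k4`; `α1 = 0` exactly for an
irreversible tracer (`k4 = 0`). A voxel's measured signal mixes in whole
blood through the blood volume fraction `fv`:

    C_PET(t) = (1 - fv) CT(t) + fv C_WB(t),      C_WB ≡ C0.

Frame values integrate `C_PET` over each acquisition interval with an
optional radioactive-decay weight `exp(-λτ)`:

    x_m = ∫_{t_m,s}^{t_m,e} C_PET(τ) e^{-λτ} dτ        (integral mode)

`λ` defaults to ln2/109.77 min⁻¹ (¹⁸F) and is configurable. Because
clinically reconstructed SUV frames are normally decay-corrected already,
schedules carry a `decay_corrected_input` flag (default true) that skips the
weight; `mode="average"` divides by frame duration, which is the convention
for SUV images and the package default. The raw integral mode reproduces
the printed definition literally.

### Numerics

* **Exact exponential-integrator convolution.** `C0` is interpolated
  piecewise-linearly (constant beyond the last sample, zero before t=0).
  The convolution with `exp(-αt)` is then evaluated *exactly* per grid
  interval via the recursion `g[n+1] = e^{-αΔ} g[n] + c[n+1]E0 - Δc·E1/Δ`
  with `Ek = ∫ u^k e^{-αu} du` (series expansion below `αΔ < 1e-5` to avoid
  cancellation). The only remaining discretisation errors are the linear
  interpolation of `C0` and the trapezoid frame integration, both O(Δt²).
  The recursion is evaluated as a blocked rescaled scan (vectorised over
  voxels), with a plain-loop fallback if the rescaling would overflow.
* **Degenerate eigenvalues.** When the discriminant vanishes (repeated
  root, e.g. `k2=k3=k4=0`), the impulse response gains a `t·exp(-αt)` term;
  the simulator switches to that closed form below a discriminant of 1e-9.
  For `k4 = 0` the exact irreversible branch (`α1 = 0`, `a = K1k3/s`,
  `b = K1k2/s`) is used outright, so no cancellation residue leaks into α1.
* **Dense grid.** Default spacing 0.05 min, which resolves the 10-s early
  frames with ≥3 interior points. Frame boundaries need not coincide with
  grid nodes: the quadrature matrix integrates the piecewise-linear
  interpolant exactly across fractional intervals.
* **Independent oracle.** `kinetics.ode_oracle` integrates the ODEs with a
  fixed-step classical RK4 (default 0.002 min) and shares no code with the
  analytic path; the two agree to relative L2 < 1e-3 across random
  parameter draws, which is the package's primary correctness anchor.

## Patlak analysis

For irreversible tracers the ratio `C_PET(t)/Cp(t)` becomes affine in
"Patlak time" `x(t) = ∫0^t Cp / Cp(t)` after equilibration, with slope
`Ki` (net influx) and intercept `V0`. The package fits ordinary least
squares over the last `n_tail = 13` frames by default. Numerical choices:

* Frames are represented by their arithmetic mid-time; the ordinate uses
  the frame-averaged activity (the standard Patlak estimator for binned
  data).
* At the voxel level the measurable slope is `(1-fv)·K1k3/(k2+k3)`: the
  blood-volume term `fv·Cp/Cp = fv` is constant and moves only the
  intercept. Tests therefore compare fitted voxel slopes against the
  `(1-fv)`-scaled closed form; the tissue-level identity
  `Ki = K1k3/(k2+k3)` is recovered at `fv = 0`.
* The residual transient of the non-trapped compartment decays like
  `exp(-(k2+k3)t)` *relative to Cp*; for very low-trapping tissue the
  fitted slope at 15–65 min retains a small negative bias. With the
  phantom's tissue classes the bias is under 3%; it is a property of
  finite-time Patlak analysis, not of the implementation.
* Voxels with non-finite inputs produce NaN in the map rather than
  aborting.

## The synthetic phantom

The generator emulates the clinical acquisition the method targets: a 1-h
dynamic FDG scan binned into 28 frames (6×10 s, 4×30 s, 4×60 s, 4×120 s,
10×300 s), of which the first 22 frames (0–35 min) are the predictor's
input and the last 6 (35–65 min) its targets.

* **Input function**: the classic Feng bolus form
  `(A1 t - A2 - A3)e^{-λ1 t} + A2 e^{-λ2 t} + A3 e^{-λ3 t}` with the
  standard FDG population parameters (peak ≈ 0.3 min, slow bi-exponential
  tail), standing in for an image-derived aortic curve. One curve serves as
  both plasma input and whole blood.
* **Geometry**: 2-D slices (default 64×64): an elliptical body of soft
  tissue containing a liver-like high-`K1` organ and 1–3 lesion-like
  high-`k3` foci; the exterior is air (no tracer), as in physical
  phantoms. Region masks partition the image exactly.
* **Kinetics**: region parameters are FDG-realistic and irreversible
  (`k4=0`), jittered multiplicatively (lognormal, 10%) per seed within
  physiological bounds (K1, k2 ∈ [0.01, 1.5], k3 ∈ [0.001, 0.5],
  k4 ∈ [0, 0.2] min⁻¹, fv ∈ [0, 0.3]). Nominal net influx: lesion 0.055,
  soft tissue 0.014, liver 0.008 min⁻¹.
* **Noise**: additive Gaussian with per-frame s.d. `noise_scale/√duration`
  (default scale 2.0 kBq/ml·min^½, i.e. ≈1.0 SUV on 10-s frames and
  ≈0.19 SUV on 5-min frames at the default 63 kg / 300 MBq scaling). This
  reproduces the defining feature of dynamic PET — early frames are far
  noisier than late ones — but not the spatial correlation, bias, or
  signal-dependence of true reconstruction noise. Consequences: tests
  demonstrate denoising/prediction behaviour under independent Gaussian
  noise only, and say nothing about artifact behaviour (e.g. motion) in
  clinical images.
* **SUV**: `SUV = C[kBq/ml] × weight[g] / dose[kBq]`, i.e. a scale factor
  `weight_kg/dose_MBq`; defaults 63 kg and 300 MBq. Patlak coordinates are
  ratios of activities, so Ki is invariant under SUV scaling.
* Everything (geometry, jitter, noise) derives from a single integer seed.

## The predictor

Two stages, trained end to end:

1. **Feature extractor** — a U-Net applied to each input frame
   independently with shared weights (frames form the batch axis, so no
   information mixes across frames or slices). Five levels with target
   channel sizes 64, 128, 256, 512, 1024; each block is
   conv3×3 → conv3×3 → GroupNorm (16 channels/group) → ReLU; 2× max-pool
   down, 2×2 transposed-convolution up, skip connections between
   same-level encoder/decoder blocks; a 1×1 output convolution yields 10
   feature maps per frame. The deepest encoder map is 1/16 of the input
   side. With 22 input frames each voxel owns a 220-dim feature vector.
2. **Kinetic-parameter head** — a pointwise (1×1 convolution) network
   220 → 256 → 128 → 64 → 5 with ReLU between layers and a final sigmoid
   scaled onto physical ranges: fv ∈ [0,1], K1, k2 ∈ [0,2], k3 ∈ [0,0.5],
   k4 ∈ [0,0.2] min⁻¹ (the phantom's physiological bounds with headroom).
   The hidden widths are a design choice; the output order is
   (fv, K1, k2, k3, k4).

The predicted parameter maps feed a **differentiable kinetic layer** that
renders all 28 frames. Its forward pass reuses the exact convolution
recursion; its backward pass uses the identity `dg/dα = -(t-weighted
convolution)` — exact for the discretised forward — plus analytic chain
rules through the macro-rates. Near-degenerate eigenvalue pairs are handled
by flooring the discriminant at 1e-6, which keeps amplitudes bounded and
gradients finite; away from that measure-zero set the layer matches the
reference simulator to better than 1e-6 relative.

A **model-free ablation** keeps the identical backbone and head widths but
maps the 220 features directly to the 6 target frames with no bounded
activation and no kinetic layer.

The whole stack is implemented in NumPy with explicit backpropagation
(layers carry `forward`/`backward` and parameter gradients); correctness is
enforced by central finite-difference checks at 1e-4 relative tolerance
through every layer including the kinetic one. Weight init is fan-in-scaled
(He) with fan-in-scaled uniform biases, all seed-controlled. Biases are
deliberately not zero-initialised: with ReLU activations, exactly-zero
pre-activations sit on the kink and break gradient verification.

## Losses and training

* `loss_SUV`: mean Huber loss (δ = 1 SUV) over the *target* frames only
  (the last 6); the 22 input frames are never supervised.
* `loss_diff`: mean Huber loss between successive-frame differences of
  `y = pred/Cp` and of `Ki·x` over the linear portion (last 13 frames).
  `Ki` is refit from the current prediction by OLS each step and treated
  as a constant (detached) — the alternative of supplying a fixed
  reference map is supported. Differencing removes intercepts, so this
  term anchors the prediction's Patlak slope only.
* `loss = loss_SUV + λ·loss_diff` with λ = 1 by default (the weighting is
  a free hyperparameter; 1 treats both terms equally and worked without
  tuning).
* Optimiser: Adam, learning rate 1e-4, divided by 10 every 10,000
  iterations, floored at 1e-7, 10 epochs — these are the reference
  hyperparameters and the package defaults. Each iteration processes one
  2-D slice.

## Desk-scale training configuration

Full-width training (64–1024 channels, tens of thousands of iterations) is
a GPU-scale undertaking. The package's desk-scale configuration — used by
the end-to-end tests and the acceptance script — trains on 128 seeded
64×64 phantom slices with random rotation/flip augmentation (exact
symmetries of the kinetics), channel widths scaled by 1/8 (8…128), head
widths 64→32, a 0.2-min kinetic-layer grid (which changes the supervised
late frames by < 0.01 SUV relative to the 0.05-min reference grid), float32
weights, and Adam at 1e-3 decayed ×0.3 after 800 of 1,200 iterations with
global gradient-norm clipping at 5 (single-slice steps have heavy-tailed
gradient noise; without the clip an occasional run drifts into a collapsed
solution that predicts near-zero influx on unseen layouts). The
learning rate is raised from the reference 1e-4 because the scaled-down
network is two orders of magnitude smaller and trains from scratch within a
far smaller iteration budget; 1e-3 with a late decay converged fastest in
short sweeps. All other loss and schedule settings are the defaults
above. At this scale the held-out parameter-recovery correlation stabilises
above 0.95 within the 1,200 iterations, while the held-out frame RMSE is
still decreasing when training stops (≈0.34 SUV after 2,400 iterations in
longer runs) — the configuration under-trains relative to its own
asymptote, and the frame-level comparisons below inherit that. The evaluation protocol
follows the clinical analysis: the predicted Ki map is fitted from the
*measured* first 22 frames plus the *predicted* last 6, and compared to
the Patlak fit of the clean full series; the 30-min baseline fits the same
13-frame tail entirely within the first 22 noisy frames.

What the desk-scale results do and do not show: the network recovers the
per-voxel net influx K₁k₃/(k₂+k₃) on held-out phantoms with voxelwise
correlation ≈0.96, demonstrating that the physics-constrained architecture
learns genuine kinetics from half-hour inputs. Its held-out frame RMSE
(≈0.34–0.4 SUV at this training scale) does not yet undercut the late-frame
noise floor of the generator (σ≈0.19 SUV on 5-min frames), and the Kᵢ map
fitted from measured-plus-predicted frames does not yet undercut the
30-minute-only Patlak baseline (≈0.0011 min⁻¹), both of which keep
improving with training length; at this scale those two comparisons favour
the baselines. None of these numbers estimate clinical performance.

## Metrics

SSIM and PSNR anchor their data range to the reference image (SSIM: 7×7
uniform window, K1=0.01, K2=0.03). NMI is `2·I(a;b)/(H(a)+H(b))` over a
64-bin joint histogram spanning the union range (the symmetric "arithmetic"
normalisation). Bland–Altman reports mean difference and 95% limits of
agreement `mean ± 1.96·sd` with the sample (n−1) standard deviation.
Percent improvements are computed per image as `(method−baseline)/baseline`
and averaged; on phantoms these are illustrative numbers, not clinical
claims.

## Known limitations

* The phantom's noise is additive, white and Gaussian; real dynamic-PET
  noise is spatially correlated and signal-dependent.
* One blood curve serves as plasma and whole blood; no metabolite or
  plasma-to-whole-blood correction.
* 2-D slices only; no scanner PSF, no attenuation/scatter physics, no
  motion.
* The Patlak fit is unweighted OLS; weighted variants and bootstrap CIs
  are out of scope.
* The kinetic layer's discriminant floor makes the (measure-zero)
  repeated-eigenvalue manifold non-smooth; training never visits it in
  practice.
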