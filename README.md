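# petkin

Dynamic FDG-PET kinetic modelling: two-tissue-compartment (2TCM) simulation,
Patlak Kᵢ parametric imaging, and a physics-constrained neural predictor that
reconstructs the last 30 minutes of a 1-hour dynamic scan from the first 30
minutes.

## The problem

Patlak Kᵢ images — the net tracer influx rate per voxel, obtained by fitting
the linear tail of the Patlak plot — are more robust quantitative readouts
than SUV, but they need about an hour of dynamic scanning. `petkin`
implements a hybrid approach: a U-Net extracts 10 feature maps from each of
the 22 early frames (0–35 min), a pointwise 1×1-convolution head maps each
voxel's 220-dim feature vector to the five 2TCM parameters
(f_v, K₁, k₂, k₃, k₄), and a differentiable kinetic layer renders the full
28-frame series from those parameters:

    C_T(t)   = a·C₀⊗e^(−α₁t) + b·C₀⊗e^(−α₂t)          (2TCM solution)
    C_PET(t) = (1−f_v)·C_T(t) + f_v·C_WB(t)            (blood-volume mixing)
    x_m      = ∫ C_PET(τ)·e^(−λτ) dτ over frame m      (frame integration)

Training minimises `loss = loss_SUV + λ·loss_diff`, a Huber frame loss on
the 6 late target frames plus a Huber loss on successive differences of the
Patlak ordinate (anchoring the predicted Kᵢ slope). Because clinical dynamic
scans are private data, the package ships a seeded 2-D phantom generator
(28-frame clinical protocol, Feng-form arterial input, region-wise FDG
kinetics, duration-scaled noise) so the entire method trains and tests at
desk scale. See `docs/methods.md` for the model, parameters and numerical
choices.

## Worked example

Simulate a phantom, fit a Patlak Kᵢ map from its *noisy* series, and compare
against the stored ground truth (the fit of the noiseless series):

```bash
$ petkin simulate --seed 11 --size 64 --out sim/
wrote phantom (seed 11, 64x64, 28 frames) to sim/

$ petkin patlak --series sim/noisy.nii.gz --blood sim/blood.csv --out fit/
fitted Ki over frames 16-28; wrote fit/

$ petkin evaluate --pred fit/ki.nii.gz --ref sim/ki_true.nii.gz
{
 "ssim": 0.9170156762501155,
 "psnr": 37.77201810795791,
 "nmi": 0.6267537862921951,
 "rmse": 0.0006031040122876638,
 "bland_altman": {
  "mean": 1.5344811614873e-05,
  "loa_low": -0.0011665006569959628,
  "loa_high": 0.0011971902802257088
 }
}
```

Reading the numbers: the noisy 13-frame fit recovers the Kᵢ map with an RMSE
of 6·10⁻⁴ min⁻¹ against voxel values of (1−f_v)·K₁k₃/(k₂+k₃) ≈ 0.05 min⁻¹ in
the lesion, 0.014 in soft tissue and 0.008 in the liver; the Bland–Altman
mean difference is ~1.5·10⁻⁵ (essentially unbiased) with 95% limits of
agreement of ±1.2·10⁻³ min⁻¹ reflecting frame noise propagated through the
least-squares slope. Fitting the *clean* series instead reproduces the
ground truth bitwise (SSIM 1, RMSE 0).

Python API in one breath:

```python
from petkin import phantom, patlak
from petkin.types import DynamicSeries

noisy, clean, params, ki_true = phantom.generate(phantom.PhantomSpec(seed=11))
blood = phantom.analytic_input_function()
km = patlak.ki_map(clean, blood, n_tail=13)   # km.ki, km.v0
```

Training the predictor (desk scale, CPU) and predicting:

```bash
petkin train --config train.yaml --out run/      # see io.RunConfig fields
petkin predict --checkpoint run/checkpoint.npz \
    --series sim/noisy.nii.gz --blood sim/blood.csv --out pred/
```

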