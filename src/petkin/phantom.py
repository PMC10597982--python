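"""Seeded synthetic dynamic-PET phantoms.

Generates 2-D slice phantoms that emulate a 1-h clinical FDG protocol:
28 frames (6x10 s, 4x30 s, 4x60 s, 4x120 s, 10x300 s), region-wise 2TCM
parameters (background, soft tissue, a liver-like high-K1 organ, and
lesion-like high-k3 foci), a Feng-form analytic arterial input function, and
additive Gaussian noise whose standard deviation shrinks with the square root
of frame duration — so the short early frames are noisy and the late 5-min
frames are clean, as in reconstructed dynamic PET.

Everything is reproducible from ``PhantomSpec.seed`` alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kinetics, patlak
from .types import BloodInput, DynamicSeries, FrameSchedule

__all__ = [
    "default_schedule",
    "FengInputSpec",
    "analytic_input_function",
    "RegionSpec",
    "PhantomSpec",
    "generate",
    "to_suv",
    "from_suv",
    "N_INPUT_FRAMES",
    "N_TARGET_FRAMES",
]

#: First 22 frames (0-35 min) feed the predictor; the last 6 (35-65 min) are
#: the prediction targets.
N_INPUT_FRAMES = 22
N_TARGET_FRAMES = 6

_FRAME_GROUPS_S = [(6, 10.0), (4, 30.0), (4, 60.0), (4, 120.0), (10, 300.0)]


def default_schedule(decay_corrected_input: bool = True) -> FrameSchedule:
    """The 28-frame 1-h clinical protocol, in minutes."""
    durations_s = np.concatenate(
        [np.full(n, d) for n, d in _FRAME_GROUPS_S])
    ends = np.cumsum(durations_s) / 60.0
    starts = ends - durations_s / 60.0
    return FrameSchedule(starts=starts, ends=ends,
                         decay_corrected_input=decay_corrected_input)


# ---------------------------------------------------------------------------
# analytic arterial input function
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FengInputSpec:
    """Feng-form arterial input function for bolus FDG injection:

        C0(t) = (A1*t - A2 - A3) exp(-l1 t) + A2 exp(-l2 t) + A3 exp(-l3 t)

    The defaults are the classic FDG population values (concentration scale
    treated as kBq/ml); the curve starts at zero, peaks within the first two
    minutes and decays slowly afterwards.
    """

    A1: float = 851.1225  # kBq/ml/min
    A2: float = 21.8798   # kBq/ml
    A3: float = 20.8113   # kBq/ml
    l1: float = 4.133859  # 1/min
    l2: float = 0.01043449
    l3: float = 0.1190996


def analytic_input_function(spec: FengInputSpec = FengInputSpec(),
                            grid: np.ndarray | None = None) -> BloodInput:
    """Sample the Feng-form curve on ``grid`` (default 0-65 min at 0.01)."""
    if grid is None:
        grid = np.arange(0.0, 65.0 + 1e-9, 0.01)
    grid = np.asarray(grid, dtype=float)
    t = grid
    v = ((spec.A1 * t - spec.A2 - spec.A3) * np.exp(-spec.l1 * t)
         + spec.A2 * np.exp(-spec.l2 * t) + spec.A3 * np.exp(-spec.l3 * t))
    if np.any(v < -1e-9 * max(spec.A2 + spec.A3, 1.0)):
        raise ValueError("input-function parameters produce a negative curve")
    return BloodInput(times=grid, values=np.maximum(v, 0.0))


# ---------------------------------------------------------------------------
# phantom geometry and parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionSpec:
    """One tissue class: a name and its 2TCM parameters (fv,K1,k2,k3,k4)."""

    name: str
    params: tuple  # (fv, K1, k2, k3, k4)


#: FDG-realistic region kinetics (1/min).  The background outside the body
#: is air (no tracer); tissue regions are irreversible (k4 = 0) so the
#: analytic net influx Ki = K1*k3/(k2+k3) is exact per region.
DEFAULT_REGIONS = (
    RegionSpec("background", (0.0, 0.0, 0.0, 0.0, 0.0)),
    RegionSpec("soft_tissue", (0.05, 0.30, 0.50, 0.025, 0.0)),
    RegionSpec("liver", (0.15, 0.90, 1.10, 0.010, 0.0)),
    RegionSpec("lesion", (0.10, 0.40, 0.50, 0.080, 0.0)),
)

#: Physiological sampling bounds for jittered parameters (1/min; fv unitless).
PARAM_BOUNDS = {
    "fv": (0.0, 0.3), "K1": (0.01, 1.5), "k2": (0.01, 1.5),
    "k3": (0.001, 0.5), "k4": (0.0, 0.2),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Configuration of one synthetic slice.

    ``noise_scale`` is the additive-noise standard deviation for a 1-min
    frame, in frame units (kBq/ml with the default input function); a frame
    of duration ``d`` minutes receives noise of s.d. ``noise_scale/sqrt(d)``.
    ``jitter`` perturbs region parameters multiplicatively (lognormal s.d. as
    a fraction) so different seeds give different but physiological tissue.
    """

    shape: tuple = (64, 64)
    regions: tuple = DEFAULT_REGIONS
    seed: int = 0
    noise_scale: float = 2.0
    jitter: float = 0.10


def _region_masks(shape, rng) -> dict:
    """Partition of the slice into the four tissue classes."""
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    cy, cx = (H - 1) / 2, (W - 1) / 2

    def ellipse(y0, x0, ry, rx):
        return ((yy - y0) / ry) ** 2 + ((xx - x0) / rx) ** 2 <= 1.0

    body = ellipse(cy, cx, 0.42 * H * rng.uniform(0.9, 1.1),
                   0.42 * W * rng.uniform(0.9, 1.1))
    liver = ellipse(cy + 0.12 * H, cx - 0.15 * W + rng.uniform(-2, 2),
                    0.16 * H, 0.20 * W) & body
    lesion = np.zeros(shape, bool)
    for _ in range(rng.integers(1, 4)):
        r = rng.uniform(0.04, 0.09) * min(H, W)
        y0 = cy + rng.uniform(-0.25, 0.25) * H
        x0 = cx + rng.uniform(-0.25, 0.25) * W
        lesion |= ellipse(y0, x0, r, r)
    lesion &= body & ~liver
    masks = {
        "background": ~body,
        "soft_tissue": body & ~liver & ~lesion,
        "liver": liver & ~lesion,
        "lesion": lesion,
    }
    return masks


def _jitter_params(params, jitter, rng):
    names = ("fv", "K1", "k2", "k3", "k4")
    out = []
    for name, v in zip(names, params):
        lo, hi = PARAM_BOUNDS[name]
        if v == 0.0 or jitter == 0.0:
            out.append(v)  # exact zeros (k4=0) stay exact
        else:
            out.append(float(np.clip(v * np.exp(jitter * rng.standard_normal()),
                                     lo, hi)))
    return tuple(out)


def build_param_maps(spec: PhantomSpec) -> np.ndarray:
    """Per-voxel (5, H, W) parameter maps for the phantom, seeded."""
    rng = np.random.default_rng(spec.seed)
    masks = _region_masks(spec.shape, rng)
    pm = np.zeros((5,) + tuple(spec.shape))
    for region in spec.regions:
        p = _jitter_params(region.params, spec.jitter, rng)
        m = masks[region.name]
        for i in range(5):
            pm[i][m] = p[i]
    return pm


def generate(spec: PhantomSpec,
             schedule: FrameSchedule | None = None,
             input_spec: FengInputSpec = FengInputSpec(),
             n_tail: int = patlak.DEFAULT_N_TAIL):
    """Generate one phantom slice.

    Returns ``(noisy, clean, param_maps, true_ki)`` where the series hold
    frame-averaged activity concentration, ``param_maps`` is the (5, H, W)
    ground truth, and ``true_ki`` is the Patlak fit of the *clean* series.
    Fully reproducible from ``spec.seed``.
    """
    if schedule is None:
        schedule = default_schedule()
    blood = analytic_input_function(input_spec)
    pm = build_param_maps(spec)
    clean = kinetics.simulate_dynamic_frames(pm, blood, schedule)
    rng = np.random.default_rng(spec.seed + 1_000_003)
    if spec.noise_scale > 0:
        sd = spec.noise_scale / np.sqrt(schedule.durations)
        noise = rng.standard_normal(clean.frames.shape) * sd[:, None, None]
        noisy_frames = clean.frames + noise
    else:
        noisy_frames = clean.frames.copy()
    noisy = DynamicSeries(frames=noisy_frames, schedule=schedule)
    true_ki = patlak.ki_map(clean, blood, n_tail=n_tail)
    return noisy, clean, pm, true_ki


def analytic_region_ki(spec: PhantomSpec) -> dict:
    """Closed-form tissue Ki = K1*k3/(k2+k3) per k4=0 region (nominal,
    un-jittered).  Note the *voxel-level* Patlak slope is (1-fv)*Ki because
    the blood-volume term contributes only to the intercept."""
    out = {}
    for region in spec.regions:
        fv, K1, k2, k3, k4 = region.params
        if k4 == 0.0:
            out[region.name] = K1 * k3 / (k2 + k3) if k2 + k3 > 0 else 0.0
    return out


def analytic_voxel_ki(param_maps: np.ndarray) -> np.ndarray:
    """Closed-form voxel-level Patlak slope (1-fv)*K1*k3/(k2+k3) for k4=0
    parameter maps (the measurable net influx of the blood-mixed voxel)."""
    fv, K1, k2, k3 = param_maps[0], param_maps[1], param_maps[2], param_maps[3]
    denom = k2 + k3
    return np.where(denom > 0, (1.0 - fv) * K1 * k3 / np.where(denom > 0, denom, 1.0), 0.0)


def suv_dataset(seeds, shape=(64, 64), noise_scale: float = 2.0,
                jitter: float = 0.10, schedule: FrameSchedule | None = None,
                input_spec: FengInputSpec = FengInputSpec(),
                weight_kg: float = 63.0, dose_MBq: float = 300.0,
                n_tail: int = patlak.DEFAULT_N_TAIL) -> list:
    """SUV-normalised phantom slices ready for training/evaluation.

    One slice per seed; each entry carries the noisy and clean SUV frames,
    the SUV-scaled blood input, the schedule, the true parameter maps and
    the clean-series Patlak Ki map.
    """
    if schedule is None:
        schedule = default_schedule()
    blood_raw = analytic_input_function(input_spec)
    f = _suv_factor(weight_kg, dose_MBq)
    blood = BloodInput(blood_raw.times, blood_raw.values * f)
    out = []
    for seed in seeds:
        spec = PhantomSpec(shape=tuple(shape), seed=int(seed),
                           noise_scale=noise_scale, jitter=jitter)
        noisy, clean, pm, tki = generate(spec, schedule, input_spec,
                                         n_tail=n_tail)
        out.append({
            "frames": noisy.frames * f,
            "clean": clean.frames * f,
            "blood": blood,
            "schedule": schedule,
            "pm": pm,
            "ki_true": tki.ki,   # Ki is a ratio: unaffected by SUV scaling
            "seed": int(seed),
        })
    return out


# ---------------------------------------------------------------------------
# SUV normalisation
# ---------------------------------------------------------------------------

def _suv_factor(weight_kg: float, dose_MBq: float) -> float:
    # SUV = C[kBq/ml] * body weight [g] / injected dose [kBq]
    if weight_kg <= 0 or dose_MBq <= 0:
        raise ValueError("weight and dose must be positive")
    return (weight_kg * 1000.0) / (dose_MBq * 1000.0)


def to_suv(series: DynamicSeries, weight_kg: float = 63.0,
           dose_MBq: float = 300.0) -> DynamicSeries:
    """Convert frame-averaged concentration (kBq/ml) to SUV.

    SUV = concentration x body weight (g) / injected dose (kBq), i.e. the
    scale factor is weight_kg / dose_MBq.
    """
    f = _suv_factor(weight_kg, dose_MBq)
    return DynamicSeries(frames=series.frames * f, schedule=series.schedule)


def from_suv(series: DynamicSeries, weight_kg: float = 63.0,
             dose_MBq: float = 300.0) -> DynamicSeries:
    """Inverse of :func:`to_suv`."""
    f = _suv_factor(weight_kg, dose_MBq)
    return DynamicSeries(frames=series.frames / f, schedule=series.schedule)
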