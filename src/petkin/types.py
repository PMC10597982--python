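"""Core domain containers for dynamic-PET kinetic analysis.

Conventions
-----------
* Time is measured in **minutes** everywhere in memory; rate constants in 1/min.
  On-disk schedule sidecars store seconds (the clinical convention) and are
  converted on read/write by :mod:`petkin.io`.
* Activity concentration units are arbitrary but must be consistent between a
  tissue curve and the blood input that generated it (kBq/ml in the phantom,
  SUV after normalisation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KineticParams",
    "MacroRates",
    "BloodInput",
    "FrameSchedule",
    "TissueCurve",
    "DynamicSeries",
    "KiMap",
    "F18_DECAY_PER_MIN",
]

#: Decay constant of 18F in 1/min (half-life 109.77 min).
F18_DECAY_PER_MIN: float = float(np.log(2.0) / 109.77)


@dataclass(frozen=True)
class KineticParams:
    """Per-voxel parameters of the two-tissue compartment model (2TCM).

    Attributes
    ----------
    fv : float
        Fractional blood volume of the voxel, in [0, 1].
    K1 : float
        Plasma -> tissue influx rate (ml/min/ml, handled as 1/min).
    k2 : float
        Tissue -> plasma efflux rate (1/min).
    k3 : float
        Nondisplaceable -> specific (bound) transfer rate (1/min).
    k4 : float
        Specific -> nondisplaceable back-transfer rate (1/min); 0 for an
        irreversible tracer.
    """

    fv: float
    K1: float
    k2: float
    k3: float
    k4: float

    def __post_init__(self) -> None:
        for name in ("fv", "K1", "k2", "k3", "k4"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.fv > 1:
            raise ValueError(f"fv must be <= 1, got {self.fv}")

    def as_array(self) -> np.ndarray:
        return np.array([self.fv, self.K1, self.k2, self.k3, self.k4])


@dataclass(frozen=True)
class MacroRates:
    """Macro-rates of the bi-exponential 2TCM impulse response.

    The tissue response to a unit plasma bolus is ``a*exp(-alpha1*t) +
    b*exp(-alpha2*t)`` with ``0 <= alpha1 <= alpha2``.  ``alpha1 == 0``
    exactly when ``k4 == 0`` (irreversible binding).
    """

    a: float
    b: float
    alpha1: float
    alpha2: float
    #: True when the eigenvalues coincide within the numerical guard and the
    #: repeated-root form a*exp(-alpha*t) + b*t*exp(-alpha*t) applies
    #: (then ``b`` carries the coefficient of the ``t * exp`` term).
    degenerate: bool = False


@dataclass(frozen=True)
class BloodInput:
    """Arterial/whole-blood activity curve C0(t) = Cp(t) = Cwb(t).

    One curve serves as both the plasma input driving the tissue compartments
    and the whole-blood signal mixed into the voxel by the blood volume
    fraction.
    """

    times: np.ndarray  # min, strictly increasing, times[0] == 0
    values: np.ndarray  # activity concentration, >= 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.shape != t.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if t[0] != 0:
            raise ValueError("blood input must start at t = 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("blood activity values must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __call__(self, t) -> np.ndarray:
        """Piecewise-linear interpolation; constant beyond the last sample,
        zero before t = 0."""
        t = np.asarray(t, dtype=float)
        out = np.interp(t, self.times, self.values)
        return np.where(t < 0, 0.0, out)

    def cumulative_integral(self, t) -> np.ndarray:
        """Running integral of the interpolated curve from 0 to each ``t``."""
        from scipy.integrate import cumulative_trapezoid

        t = np.atleast_1d(np.asarray(t, dtype=float))
        # integrate on the union grid so sample kinks are respected
        grid = np.union1d(self.times, t[t >= 0])
        cum = cumulative_trapezoid(self(grid), grid, initial=0.0)
        out = np.interp(t, grid, cum)
        return np.where(t < 0, 0.0, out)


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered acquisition frames with the radiotracer decay constant.

    ``starts``/``ends`` are in minutes; ``decay_lambda`` in 1/min.
    ``decay_corrected_input`` records whether frame values are already
    decay-corrected, in which case the exp(-lambda*t) weight is skipped when
    integrating a concentration curve into frames.
    """

    starts: np.ndarray
    ends: np.ndarray
    decay_lambda: float = F18_DECAY_PER_MIN
    decay_corrected_input: bool = True

    def __post_init__(self) -> None:
        s = np.asarray(self.starts, dtype=float)
        e = np.asarray(self.ends, dtype=float)
        if s.ndim != 1 or e.shape != s.shape:
            raise ValueError("starts and ends must be 1-D arrays of equal length")
        if np.any(s >= e):
            raise ValueError("each frame must have start < end")
        if np.any(e[:-1] > s[1:] + 1e-12):
            raise ValueError("frames must not overlap")
        if self.decay_lambda < 0:
            raise ValueError("decay_lambda must be >= 0")
        object.__setattr__(self, "starts", s)
        object.__setattr__(self, "ends", e)

    @property
    def n_frames(self) -> int:
        return len(self.starts)

    @property
    def durations(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def mid_times(self) -> np.ndarray:
        return 0.5 * (self.starts + self.ends)

    def subset(self, index) -> "FrameSchedule":
        return FrameSchedule(
            self.starts[index],
            self.ends[index],
            self.decay_lambda,
            self.decay_corrected_input,
        )


@dataclass(frozen=True)
class TissueCurve:
    """Compartment concentrations on a dense time grid.

    ``ct = c1 + c2`` pointwise; ``cpet`` is the blood-mixed voxel signal and
    is filled in by :func:`petkin.kinetics.voxel_concentration`.
    """

    times: np.ndarray
    c1: np.ndarray
    c2: np.ndarray
    ct: np.ndarray
    cpet: np.ndarray | None = None


@dataclass
class DynamicSeries:
    """A stack of frame images (T, H, W) with its acquisition schedule.

    ``frames`` may hold frame-averaged activity concentration (the SUV-style
    convention, default throughout) or the raw frame integral, depending on
    how it was produced.
    """

    frames: np.ndarray
    schedule: FrameSchedule

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=float)
        if f.ndim == 1:
            f = f[:, None, None]
        if f.ndim != 3:
            raise ValueError("frames must be (T, H, W)")
        if f.shape[0] != self.schedule.n_frames:
            raise ValueError(
                f"frame count {f.shape[0]} does not match schedule "
                f"({self.schedule.n_frames} frames)"
            )
        self.frames = f

    @property
    def shape(self) -> tuple:
        return self.frames.shape


@dataclass
class KiMap:
    """Per-voxel Patlak net-influx slope Ki (1/min) and intercept V0."""

    ki: np.ndarray
    v0: np.ndarray
    fit_frames: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.ki = np.asarray(self.ki, dtype=float)
        self.v0 = np.asarray(self.v0, dtype=float)
        if self.ki.shape != self.v0.shape:
            raise ValueError("ki and v0 must have the same shape")
        self.fit_frames = np.asarray(self.fit_frames, dtype=int)
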