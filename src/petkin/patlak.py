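"""Patlak graphical analysis: coordinates, tail fitting, and Ki/V0 maps.

For an irreversibly trapped tracer the tissue-to-plasma ratio becomes an
affine function of "Patlak time" once the reversible compartments have
equilibrated:

    C_tissue(t) / Cp(t)  =  Ki * (integral_0^t Cp) / Cp(t)  +  V0

The slope Ki is the net influx rate (K1*k3/(k2+k3) in the irreversible 2TCM
limit) and the intercept V0 the apparent distribution volume of non-trapped
tracer.  The fit is an ordinary least squares line over the last ``n_tail``
frames (the linear portion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import BloodInput, DynamicSeries, KiMap

__all__ = [
    "PatlakPoints",
    "patlak_coordinates",
    "fit_ki",
    "ki_map",
    "patlak_differences",
    "DEFAULT_N_TAIL",
]

#: Default number of tail frames treated as the linear portion.
DEFAULT_N_TAIL = 13


@dataclass(frozen=True)
class PatlakPoints:
    """Patlak plot coordinates.

    ``x`` is normalized integrated plasma (min), shared across voxels;
    ``y`` is the tissue-to-plasma ratio, shape ``(T,) + image_shape``.
    """

    x: np.ndarray
    y: np.ndarray
    frame_mid_times: np.ndarray


def patlak_x(blood: BloodInput, mid_times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalized integrated plasma x(t) and Cp(t) at frame mid-times."""
    mid = np.asarray(mid_times, dtype=float)
    cp = blood(mid)
    if np.any(cp <= 0):
        raise ValueError("plasma activity vanishes at a frame mid-time; "
                         "Patlak coordinates undefined")
    return blood.cumulative_integral(mid) / cp, cp


def patlak_coordinates(series: DynamicSeries, blood: BloodInput) -> PatlakPoints:
    """Per-voxel Patlak coordinates from a frame-averaged dynamic series.

    Each frame is represented by its arithmetic mid-time; ``y`` divides the
    frame's (average-mode) activity by the plasma concentration at that time,
    ``x`` divides the running plasma integral by the same.
    """
    mid = series.schedule.mid_times
    x, cp = patlak_x(blood, mid)
    y = series.frames / cp[:, None, None]
    return PatlakPoints(x=x, y=y, frame_mid_times=mid)


def fit_ki(points: PatlakPoints, n_tail: int = DEFAULT_N_TAIL):
    """OLS slope/intercept over the last ``n_tail`` Patlak points.

    Returns ``(ki, v0)`` with the shape of a single frame (scalars for a
    single-voxel series).  Voxels containing non-finite points yield NaN.
    """
    if n_tail < 2:
        raise ValueError("need at least 2 tail points for a line fit")
    if len(points.x) < n_tail:
        raise ValueError(
            f"insufficient points: need {n_tail} tail frames, have {len(points.x)}")
    x = points.x[-n_tail:]
    y = points.y[-n_tail:]
    xm = x.mean()
    xc = x - xm
    sxx = float(xc @ xc)
    ym = y.mean(axis=0)
    ki = np.tensordot(xc, y, axes=(0, 0)) / sxx
    v0 = ym - ki * xm
    bad = ~np.isfinite(y).all(axis=0)
    if np.any(bad):
        ki = np.where(bad, np.nan, ki)
        v0 = np.where(bad, np.nan, v0)
    if ki.ndim == 2 and ki.shape == (1, 1):
        return float(ki[0, 0]), float(v0[0, 0])
    return ki, v0


def ki_map(series: DynamicSeries, blood: BloodInput,
           n_tail: int = DEFAULT_N_TAIL) -> KiMap:
    """Voxelwise Patlak fit of a dynamic series into a Ki/V0 map."""
    points = patlak_coordinates(series, blood)
    ki, v0 = fit_ki(points, n_tail=n_tail)
    ki = np.atleast_2d(ki)
    v0 = np.atleast_2d(v0)
    fit_frames = np.arange(series.schedule.n_frames - n_tail,
                           series.schedule.n_frames)
    return KiMap(ki=ki, v0=v0, fit_frames=fit_frames)


def patlak_differences(series: DynamicSeries, blood: BloodInput,
                       linear_frames: np.ndarray | None = None,
                       n_tail: int = DEFAULT_N_TAIL):
    """Successive-frame differences of the Patlak coordinates.

    Returns ``(dy, dx)`` where ``dy`` are first differences of the
    tissue-to-plasma ratio along the linear-portion frames (per voxel) and
    ``dx`` the matching differences of normalized integrated plasma, so a
    perfectly linear voxel satisfies ``dy = Ki * dx``.
    """
    if linear_frames is None:
        linear_frames = np.arange(series.schedule.n_frames - n_tail,
                                  series.schedule.n_frames)
    linear_frames = np.asarray(linear_frames, dtype=int)
    if len(linear_frames) < 2:
        raise ValueError("need at least 2 linear-portion frames to difference")
    sub = DynamicSeries(series.frames[linear_frames],
                        series.schedule.subset(linear_frames))
    pts = patlak_coordinates(sub, blood)
    return np.diff(pts.y, axis=0), np.diff(pts.x)
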