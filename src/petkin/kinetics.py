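"""Forward models of the two-tissue compartment system (2TCM).

The tissue response to the plasma input ``C0(t)`` is the bi-exponential
convolution

    C_T(t) = a * C0(t) (x) exp(-alpha1 t)  +  b * C0(t) (x) exp(-alpha2 t)

with macro-rates (a, b, alpha1, alpha2) determined by (K1, k2, k3, k4).
Convolutions are evaluated *exactly* for the piecewise-linear interpolant of
the blood input (exponential-integrator recursion), so the only discretisation
error left is the linear interpolation of ``C0`` itself and the trapezoid
frame integration; both shrink as O(dt^2) with the dense-grid spacing.

A fixed-step 4th-order Runge-Kutta integration of the underlying ODEs is
provided as an independent numerical oracle (:func:`ode_oracle`); it shares no
code with the analytic path.
"""

from __future__ import annotations

import numpy as np

from .types import (
    BloodInput,
    DynamicSeries,
    FrameSchedule,
    KineticParams,
    MacroRates,
    TissueCurve,
)

__all__ = [
    "macro_rates",
    "tissue_concentration",
    "ode_oracle",
    "voxel_concentration",
    "frame_activity",
    "simulate_dynamic_frames",
    "frame_quadrature",
    "DEFAULT_GRID_DT",
]

#: Default dense-grid spacing (min) for convolutions and frame integrals.
#: Resolves the 10-s early frames with >= 3 interior points.
DEFAULT_GRID_DT = 0.05

#: Guard below which the two eigenvalues are treated as a repeated root.
EIGEN_EPS = 1e-9


# ---------------------------------------------------------------------------
# macro rates
# ---------------------------------------------------------------------------

def macro_rates(params: KineticParams, eps: float = EIGEN_EPS) -> MacroRates:
    """Macro-rates (a, b, alpha1, alpha2) of the 2TCM impulse response.

    The eigenvalues are the roots of ``s^2 + (k2+k3+k4) s + k2*k4 = 0``
    (negated), so ``alpha1 + alpha2 = k2+k3+k4`` and ``alpha1*alpha2 =
    k2*k4``.  When the discriminant falls below ``eps`` the repeated-root
    limit applies: the impulse response becomes
    ``K1 * (1 + (k3+k4-alpha) t) * exp(-alpha t)`` and the returned ``b``
    holds the coefficient of the ``t*exp`` term, flagged by ``degenerate``.
    """
    K1, k2, k3, k4 = params.K1, params.k2, params.k3, params.k4
    s = k2 + k3 + k4
    disc = float(np.sqrt(max(s * s - 4.0 * k2 * k4, 0.0)))
    alpha1 = 0.5 * (s - disc)
    alpha2 = 0.5 * (s + disc)
    if k4 == 0.0:
        # exact irreversible limit, no cancellation residue; the amplitudes
        # a = K1 k3/s, b = K1 k2/s stay bounded for any s > 0
        if s == 0.0:
            return MacroRates(a=K1, b=0.0, alpha1=0.0, alpha2=0.0,
                              degenerate=True)
        return MacroRates(a=K1 * k3 / s, b=K1 * k2 / s, alpha1=0.0,
                          alpha2=s, degenerate=False)
    if disc < eps:
        alpha = 0.5 * s
        return MacroRates(a=K1, b=K1 * (k3 + k4 - alpha), alpha1=alpha,
                          alpha2=alpha, degenerate=True)
    a = K1 * (k3 + k4 - alpha1) / disc
    b = K1 - a  # == K1*(alpha2-k3-k4)/disc, exact by Vieta
    return MacroRates(a=a, b=b, alpha1=alpha1, alpha2=alpha2, degenerate=False)


# ---------------------------------------------------------------------------
# exact convolution with exp(-alpha t) for piecewise-linear inputs
# ---------------------------------------------------------------------------

def _ek_coeffs(alpha, dt):
    """Interval coefficients for the exponential integrator.

    Returns ``(r, E0, E1, E2)`` where ``r = exp(-alpha*dt)`` and
    ``Ek = integral_0^dt u^k exp(-alpha u) du``.  Small ``alpha*dt`` uses a
    series expansion to avoid cancellation.  All inputs broadcast.
    """
    alpha = np.asarray(alpha, dtype=float)
    dt = np.asarray(dt, dtype=float)
    x = alpha * dt
    r = np.exp(-x)
    small = x < 1e-5
    with np.errstate(divide="ignore", invalid="ignore"):
        E0 = np.where(small, dt * (1.0 - x / 2.0 + x * x / 6.0),
                      (1.0 - r) / np.where(small, 1.0, alpha))
        E1 = np.where(small, dt * dt * (0.5 - x / 3.0 + x * x / 8.0),
                      (1.0 - (1.0 + x) * r) / np.where(small, 1.0, alpha) ** 2)
        E2 = np.where(small, dt ** 3 * (1.0 / 3.0 - x / 4.0 + x * x / 10.0),
                      (2.0 - (2.0 + 2.0 * x + x * x) * r)
                      / np.where(small, 1.0, alpha) ** 3)
    return r, E0, E1, E2


def _scan_linear_recurrence(z: np.ndarray, r: np.ndarray,
                            block: int = 64) -> np.ndarray:
    """Solve ``y[n] = r[n]*y[n-1] + z[n]`` along axis 0 with ``y[-1] = 0``.

    ``z`` has shape (G, ...); ``r`` broadcasts against it.  Evaluated in
    blocks via rescaled cumulative products:
    ``y[i] = P[i] * (carry + cumsum(z[i]/P[i]))`` with ``P`` the running
    product of ``r`` inside the block.  If the rescaling under/overflows
    (pathologically fast decay) the block falls back to the plain loop.
    """
    z = np.asarray(z, dtype=float)
    G = z.shape[0]
    r = np.broadcast_to(np.asarray(r, dtype=float), z.shape)
    out = np.empty_like(z)
    carry = np.zeros(z.shape[1:], dtype=float)
    for start in range(0, G, block):
        stop = min(start + block, G)
        rb = r[start:stop]
        zb = z[start:stop]
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            P = np.cumprod(rb, axis=0)
            yb = P * (carry + np.cumsum(zb / P, axis=0))
        if not np.all(np.isfinite(yb)):
            yb = np.empty_like(zb)
            prev = carry
            for i in range(stop - start):
                prev = rb[i] * prev + zb[i]
                yb[i] = prev
        out[start:stop] = yb
        carry = out[stop - 1]
    return out


def _scan_uniform(z: np.ndarray, r: np.ndarray, max_log: float = 30.0,
                  alpha_max: float | None = None,
                  x_max: float | None = None) -> np.ndarray:
    """Scan for a constant per-column decay factor ``r`` (shape (V,)).

    Solves ``y[0] = z[0]; y[n] = r*y[n-1] + z[n]`` via blocked rescaling
    ``y[i] = P[i] * (carry + cumsum(z[i]/P[i]))`` with ``P[i] = r**(i+1)``
    precomputed once; the block length is capped so the rescaling stays well
    inside double range (``x_max`` is the largest ``alpha*dt``).
    """
    G, V = z.shape[0], z.shape[1:]
    if x_max is None:
        x_max = float(-np.log(max(r.min(), 1e-300)))
    block = int(max(4, min(128, max_log / max(x_max, 1e-9))))
    L = min(block, G)
    P = np.cumprod(np.broadcast_to(r, (L,) + V), axis=0)
    invP = 1.0 / P
    out = np.empty_like(z)
    carry = np.zeros(V, dtype=z.dtype)
    for start in range(0, G, block):
        stop = min(start + block, G)
        n = stop - start
        yb = P[:n] * (carry + np.cumsum(z[start:stop] * invP[:n], axis=0))
        out[start:stop] = yb
        carry = out[stop - 1]
    return out


def exp_conv(times: np.ndarray, values: np.ndarray, alpha,
             with_t_weight: bool = False):
    """Convolution of a piecewise-linear curve with ``exp(-alpha t)``.

    Computes ``g(t_n) = integral_0^{t_n} values(s) exp(-alpha (t_n - s)) ds``
    exactly for the linear interpolant of ``values`` on ``times``.  ``alpha``
    may be an array (vectorised over voxels); the result has shape
    ``(len(times),) + alpha.shape``.

    With ``with_t_weight`` also returns
    ``h(t_n) = integral values(s) (t_n - s) exp(-alpha (t_n - s)) ds``,
    which equals ``-d g / d alpha`` of the discretised ``g`` exactly.
    """
    alpha = np.atleast_1d(np.asarray(alpha))
    if alpha.dtype != np.float32:
        alpha = alpha.astype(float)
    work = alpha.dtype  # float32 in, float32 through (training fast path)
    t = np.asarray(times, dtype=float)
    c = np.asarray(values, dtype=work)
    G = len(t)
    dt = np.diff(t)  # (G-1,)
    shape_extra = alpha.shape

    uniform = np.ptp(dt) < 1e-12 * dt[0]
    if uniform:
        d0 = float(dt[0])
        r, E0, E1, E2 = _ek_coeffs(alpha, d0)  # all (V,)
        cn = c[1:, None]
        dc = np.diff(c)[:, None]
        z = np.zeros((G,) + shape_extra, dtype=work)
        z[1:] = cn * E0[None, :] - dc * (E1 / d0)[None, :]
        x_max = float(alpha.max()) * d0
        g = _scan_uniform(z, r, x_max=x_max)
        if not with_t_weight:
            return g
        zh = np.zeros((G,) + shape_extra, dtype=work)
        zh[1:] = (r[None, :] * d0) * g[:-1] + cn * E1[None, :] \
            - dc * (E2 / d0)[None, :]
        h = _scan_uniform(zh, r, x_max=x_max)
        return g, h

    r, E0, E1, E2 = _ek_coeffs(alpha[None, :], dt[:, None])  # (G-1, V)
    cn = c[1:, None]          # c_{n+1}
    dc = np.diff(c)[:, None]  # c_{n+1} - c_n

    z = np.zeros((G,) + shape_extra)
    z[1:] = cn * E0 - dc * E1 / dt[:, None]
    rfull = np.ones((G,) + shape_extra)
    rfull[1:] = np.broadcast_to(r, (G - 1,) + shape_extra)
    g = _scan_linear_recurrence(z, rfull)
    if not with_t_weight:
        return g
    # h recursion: h[n] = r[n]*(h[n-1] + dt[n]*g[n-1]) + local[n]
    zh = np.zeros((G,) + shape_extra)
    zh[1:] = (rfull[1:] * dt[:, None] * g[:-1]
              + cn * E1 - dc * E2 / dt[:, None])
    h = _scan_linear_recurrence(zh, rfull)
    return g, h


# ---------------------------------------------------------------------------
# tissue / voxel curves
# ---------------------------------------------------------------------------

def _check_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2:
        raise ValueError("time grid must be 1-D with at least 2 points")
    if grid[0] < 0:
        raise ValueError("invalid grid: precedes time 0")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("time grid must be strictly increasing")
    return grid


def _conv_grid(grid: np.ndarray, dt: float = DEFAULT_GRID_DT) -> np.ndarray:
    """Internal grid starting at 0 containing all requested points."""
    if grid[0] == 0.0:
        return grid
    lead = np.arange(0.0, grid[0], dt)
    return np.concatenate([lead, grid])


def tissue_concentration(params: KineticParams, blood: BloodInput,
                         grid: np.ndarray) -> TissueCurve:
    """Analytic 2TCM tissue curve on ``grid`` (minutes).

    ``ct`` is the bi-exponential convolution of the interpolated blood input;
    ``c2`` is recovered from its own convolution form
    ``K1*k3/(alpha2-alpha1) * C0 (x) (exp(-alpha1 t) - exp(-alpha2 t))`` and
    ``c1 = ct - c2``.
    """
    grid = _check_grid(grid)
    work = _conv_grid(grid)
    c0 = blood(work)
    mr = macro_rates(params)
    if mr.degenerate:
        g, h = exp_conv(work, c0, mr.alpha1, with_t_weight=True)
        g, h = g[:, 0], h[:, 0]
        ct = params.K1 * g + mr.b * h
        c2 = params.K1 * params.k3 * h
    else:
        g = exp_conv(work, c0, np.array([mr.alpha1, mr.alpha2]))
        ct = mr.a * g[:, 0] + mr.b * g[:, 1]
        c2 = params.K1 * params.k3 / (mr.alpha2 - mr.alpha1) * (g[:, 0] - g[:, 1])
    c1 = ct - c2
    if len(work) != len(grid):  # drop the lead-in points
        sel = np.searchsorted(work, grid)
        c1, c2, ct = c1[sel], c2[sel], ct[sel]
    return TissueCurve(times=grid, c1=c1, c2=c2, ct=ct)


def ode_oracle(params: KineticParams, blood: BloodInput, grid: np.ndarray,
               step: float = 0.002, check_step: bool = False,
               step_tol: float = 1e-6) -> TissueCurve:
    """Fixed-step RK4 integration of the 2TCM ODEs.

    Independent numerical oracle for :func:`tissue_concentration`; shares no
    code with the analytic path.  ``check_step`` re-integrates with half the
    step and raises if the relative L2 difference exceeds ``step_tol``.
    """
    grid = _check_grid(grid)

    def integrate(h: float):
        t_end = grid[-1]
        n = int(np.ceil(t_end / h))
        ts = np.linspace(0.0, n * h, n + 1)
        K1, k2, k3, k4 = params.K1, params.k2, params.k3, params.k4

        def deriv(t, y):
            c0 = blood(t)
            d1 = K1 * c0 - (k2 + k3) * y[0] + k4 * y[1]
            d2 = k3 * y[0] - k4 * y[1]
            return np.array([d1, d2])

        ys = np.zeros((n + 1, 2))
        y = np.zeros(2)
        for i in range(n):
            t = ts[i]
            k_1 = deriv(t, y)
            k_2 = deriv(t + h / 2, y + h / 2 * k_1)
            k_3 = deriv(t + h / 2, y + h / 2 * k_2)
            k_4 = deriv(t + h, y + h * k_3)
            y = y + h / 6 * (k_1 + 2 * k_2 + 2 * k_3 + k_4)
            ys[i + 1] = y
        c1 = np.interp(grid, ts, ys[:, 0])
        c2 = np.interp(grid, ts, ys[:, 1])
        return c1, c2

    c1, c2 = integrate(step)
    if check_step:
        c1h, c2h = integrate(step / 2)
        ref = np.linalg.norm(c1h + c2h) or 1.0
        if np.linalg.norm((c1 + c2) - (c1h + c2h)) / ref > step_tol:
            raise RuntimeError("ODE step size too coarse for requested tolerance")
        c1, c2 = c1h, c2h
    return TissueCurve(times=grid, c1=c1, c2=c2, ct=c1 + c2)


def voxel_concentration(curve: TissueCurve, blood: BloodInput,
                        fv: float) -> TissueCurve:
    """Mix whole-blood signal into the tissue curve:
    ``C_PET = (1-fv)*C_T + fv*C_WB``."""
    if not 0.0 <= fv <= 1.0:
        raise ValueError(f"blood volume fraction must be in [0, 1], got {fv}")
    cwb = blood(curve.times)
    cpet = (1.0 - fv) * curve.ct + fv * cwb
    return TissueCurve(times=curve.times, c1=curve.c1, c2=curve.c2,
                       ct=curve.ct, cpet=cpet)


# ---------------------------------------------------------------------------
# frame integration
# ---------------------------------------------------------------------------

def _cumweights(grid: np.ndarray, t: float) -> np.ndarray:
    """Node weights w such that w @ f = integral_grid[0]^t of the linear
    interpolant of f."""
    G = len(grid)
    w = np.zeros(G)
    if t <= grid[0]:
        return w
    j = int(np.searchsorted(grid, t, side="right") - 1)
    j = min(j, G - 2)
    d = np.diff(grid)
    # full intervals up to j: trapezoid
    w[:j] += 0.5 * d[:j]
    w[1:j + 1] += 0.5 * d[:j]
    # partial interval [grid[j], t]
    th = (t - grid[j]) / d[j]
    w[j] += d[j] * th * (1.0 - th / 2.0)
    w[j + 1] += d[j] * th * th / 2.0
    return w


def frame_quadrature(grid: np.ndarray, schedule: FrameSchedule,
                     mode: str = "average") -> np.ndarray:
    """Quadrature matrix Q (T, G) mapping dense-grid samples to frame values.

    ``Q @ f`` integrates the piecewise-linear interpolant of ``f`` over each
    frame, weighting the integrand by ``exp(-lambda t)`` unless the schedule
    is flagged decay-corrected.  ``mode='average'`` divides by the frame
    duration (the SUV-image convention); ``mode='integral'`` leaves the raw
    decay-weighted frame integral.
    """
    if mode not in ("average", "integral"):
        raise ValueError(f"unknown mode {mode!r}")
    grid = np.asarray(grid, dtype=float)
    if schedule.starts[0] < grid[0] - 1e-12 or schedule.ends[-1] > grid[-1] + 1e-9:
        raise ValueError("frame schedule extends outside the time grid")
    Q = np.empty((schedule.n_frames, len(grid)))
    for m in range(schedule.n_frames):
        Q[m] = (_cumweights(grid, schedule.ends[m])
                - _cumweights(grid, schedule.starts[m]))
    if not schedule.decay_corrected_input and schedule.decay_lambda > 0:
        Q = Q * np.exp(-schedule.decay_lambda * grid)[None, :]
    if mode == "average":
        Q = Q / schedule.durations[:, None]
    return Q


def frame_activity(curve: TissueCurve, schedule: FrameSchedule,
                   mode: str = "average") -> DynamicSeries:
    """Integrate a voxel concentration curve into scheduled frame values.

    Uses ``curve.cpet`` if present (blood-mixed voxel signal), else
    ``curve.ct``.  Returns a single-voxel :class:`DynamicSeries`.
    """
    f = curve.cpet if curve.cpet is not None else curve.ct
    Q = frame_quadrature(curve.times, schedule, mode=mode)
    return DynamicSeries(frames=Q @ f, schedule=schedule)


# ---------------------------------------------------------------------------
# vectorised simulator
# ---------------------------------------------------------------------------

def macro_rates_arrays(K1, k2, k3, k4, eps: float = EIGEN_EPS):
    """Vectorised macro-rates; returns (a, b, alpha1, alpha2, degenerate).

    On degenerate voxels (repeated eigenvalue) the returned ``a``/``b`` carry
    the repeated-root coefficients (see :func:`macro_rates`).
    """
    s = k2 + k3 + k4
    disc = np.sqrt(np.maximum(s * s - 4.0 * k2 * k4, 0.0))
    irr = k4 == 0
    disc = np.where(irr, s, disc)
    alpha1 = np.where(irr, 0.0, 0.5 * (s - disc))
    alpha2 = np.where(irr, s, 0.5 * (s + disc))
    # repeated root: reversible voxels with a vanishing discriminant, or the
    # fully degenerate irreversible case k2 = k3 = k4 = 0
    deg = np.where(irr, s == 0.0, disc < eps)
    safe = np.where(deg, 1.0, disc)
    a = np.where(deg, K1, K1 * (k3 + k4 - alpha1) / safe)
    b = np.where(deg, K1 * (k3 + k4 - 0.5 * s), K1 - a)
    alpha1 = np.where(deg, 0.5 * s, alpha1)
    alpha2 = np.where(deg, 0.5 * s, alpha2)
    return a, b, alpha1, alpha2, deg


def simulate_dynamic_frames(param_maps: np.ndarray, blood: BloodInput,
                            schedule: FrameSchedule, mode: str = "average",
                            grid_dt: float = DEFAULT_GRID_DT) -> DynamicSeries:
    """Simulate a dynamic frame series from per-voxel 2TCM parameter maps.

    ``param_maps`` has shape (5, H, W) ordered (fv, K1, k2, k3, k4).
    Voxelwise identical to the scalar chain
    ``tissue_concentration -> voxel_concentration -> frame_activity``.
    """
    pm = np.asarray(param_maps, dtype=float)
    if pm.ndim != 3 or pm.shape[0] != 5:
        raise ValueError("param_maps must have shape (5, H, W): fv,K1,k2,k3,k4")
    if not np.all(np.isfinite(pm)):
        bad = np.argwhere(~np.isfinite(pm).all(axis=0))
        raise ValueError(f"non-finite kinetic parameters at voxels {bad[:5].tolist()}")
    if np.any(pm < 0) or np.any(pm[0] > 1):
        bad = np.argwhere((pm < 0).any(axis=0) | (pm[0] > 1))
        raise ValueError(f"kinetic parameters out of range at voxels {bad[:5].tolist()}")
    H, W = pm.shape[1:]

    # piecewise-constant maps are common (region phantoms): simulate each
    # distinct parameter vector once and scatter back — numerically identical
    # to the full per-voxel evaluation
    flat = pm.reshape(5, -1)
    uniq, inverse = np.unique(flat.T, axis=0, return_inverse=True)
    if uniq.shape[0] < flat.shape[1]:
        frames_u = _simulate_columns(uniq.T, blood, schedule, mode, grid_dt)
        frames = frames_u[:, inverse]
        return DynamicSeries(frames=frames.reshape(schedule.n_frames, H, W),
                             schedule=schedule)
    frames = _simulate_columns(flat, blood, schedule, mode, grid_dt)
    return DynamicSeries(frames=frames.reshape(schedule.n_frames, H, W),
                         schedule=schedule)


def _simulate_columns(pm: np.ndarray, blood: BloodInput,
                      schedule: FrameSchedule, mode: str,
                      grid_dt: float) -> np.ndarray:
    """Frame values (T, V) for a (5, V) array of parameter vectors."""
    fv, K1, k2, k3, k4 = (pm[i] for i in range(5))

    grid = np.arange(0.0, schedule.ends[-1] + grid_dt / 2, grid_dt)
    if grid[-1] < schedule.ends[-1]:
        grid = np.append(grid, schedule.ends[-1])
    c0 = blood(grid)
    a, b, alpha1, alpha2, deg = macro_rates_arrays(K1, k2, k3, k4)

    need_h = bool(np.any(deg))
    if need_h:
        g1, h1 = exp_conv(grid, c0, alpha1, with_t_weight=True)
        g2 = exp_conv(grid, c0, alpha2)
        ct = np.where(deg[None, :], a[None] * g1 + b[None] * h1,
                      a[None] * g1 + b[None] * g2)
    else:
        g1 = exp_conv(grid, c0, alpha1)
        g2 = exp_conv(grid, c0, alpha2)
        ct = a[None, :] * g1 + b[None, :] * g2
    cpet = (1.0 - fv)[None, :] * ct + fv[None, :] * c0[:, None]

    Q = frame_quadrature(grid, schedule, mode=mode)
    return Q @ cpet  # (T, V)
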