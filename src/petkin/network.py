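"""The two-stage frame predictor.

A shared-weight U-Net encodes each input frame of the dynamic series into 10
feature maps; the concatenated per-voxel feature vector (22 frames x 10 = 220
dims) feeds a pointwise (1x1 convolution) head that predicts the five 2TCM
parameters (fv, K1, k2, k3, k4) per voxel through a bounded (scaled sigmoid)
output.  A differentiable kinetic layer then renders the full dynamic series
from the parameters, so the frame loss trains the whole stack end to end.

A model-free ablation (:class:`WithoutModelNet`) keeps the identical backbone
but maps the 220 features directly to the 6 target frames with no bounded
activation and no kinetic layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .kinetics import DEFAULT_GRID_DT, exp_conv, frame_quadrature
from .types import BloodInput, FrameSchedule

__all__ = [
    "EncoderSpec", "ParamRanges", "UNetFeatureExtractor", "PointwiseHead",
    "KineticLayer", "HybridModel", "WithoutModelNet",
]


@dataclass(frozen=True)
class EncoderSpec:
    """U-Net feature extractor configuration.

    Defaults are the full-fidelity architecture: five levels with target
    channel sizes 64-1024 (so the deepest encoder map is 1/16 of the input
    side), 16 channels per GroupNorm group, 10 feature maps per frame and 22
    input frames.  ``scaled`` returns a narrow variant for CPU training; the
    level count and every contract except the widths are unchanged.
    """

    channel_sizes: tuple = (64, 128, 256, 512, 1024)
    groupnorm_channels_per_group: int = 16
    features_per_frame: int = 10
    input_frames: int = 22

    @property
    def feature_dim(self) -> int:
        return self.features_per_frame * self.input_frames

    def scaled(self, channel_scale: float) -> "EncoderSpec":
        cs = tuple(max(4, int(round(c * channel_scale)))
                   for c in self.channel_sizes)
        return EncoderSpec(cs, self.groupnorm_channels_per_group,
                           self.features_per_frame, self.input_frames)


@dataclass(frozen=True)
class ParamRanges:
    """Per-parameter (lo, hi) bounds mapping the head's sigmoid output onto
    physical kinetic parameters, ordered (fv, K1, k2, k3, k4)."""

    lo: tuple = (0.0, 0.0, 0.0, 0.0, 0.0)
    hi: tuple = (1.0, 2.0, 2.0, 0.5, 0.2)

    def __post_init__(self):
        if len(self.lo) != len(self.hi):
            raise ValueError("lo and hi must have equal length")
        if any(l >= h for l, h in zip(self.lo, self.hi)):
            raise ValueError("require lo < hi for every parameter")
        if self.lo[0] < 0 or self.hi[0] > 1:
            raise ValueError("fv range must lie within [0, 1]")

    def arrays(self):
        return np.asarray(self.lo, float), np.asarray(self.hi, float)


class _ScaledSigmoid(nn.Module):
    """Per-channel sigmoid scaled into [lo, hi]."""

    def __init__(self, ranges: ParamRanges):
        lo, hi = ranges.arrays()
        self.lo = lo[None, :, None, None]
        self.span = (hi - lo)[None, :, None, None]

    def forward(self, x):
        self._s = 1.0 / (1.0 + np.exp(-x))
        return self.lo + self.span * self._s

    def backward(self, dy):
        return dy * self.span * self._s * (1.0 - self._s)


class _DoubleConv(nn.Module):
    """conv3x3 -> conv3x3 -> GroupNorm -> ReLU (normalisation and activation
    follow the convolution pair)."""

    def __init__(self, cin, cout, cpg, rng, dtype):
        self.conv1 = nn.Conv2d(cin, cout, 3, rng, dtype)
        self.conv2 = nn.Conv2d(cout, cout, 3, rng, dtype)
        self.gn = nn.GroupNorm(cout, cpg, dtype=dtype)
        self.act = nn.ReLU()

    def forward(self, x):
        return self.act.forward(self.gn.forward(
            self.conv2.forward(self.conv1.forward(x))))

    def backward(self, dy):
        return self.conv1.backward(self.conv2.backward(
            self.gn.backward(self.act.backward(dy))))


class UNetFeatureExtractor(nn.Module):
    """Per-frame U-Net: 4 max-pool downsamplings, 4 transposed-convolution
    upsamplings, skip connections between same-level encoder/decoder blocks,
    and a 1x1 output convolution to ``features_per_frame`` channels.

    Frames are processed independently with shared weights (the frame axis is
    the batch axis), so there is no mixing across frames or slices.
    """

    def __init__(self, spec: EncoderSpec = EncoderSpec(),
                 rng: np.random.Generator | None = None, dtype=np.float64):
        rng = rng or np.random.default_rng()
        cs = spec.channel_sizes
        cpg = spec.groupnorm_channels_per_group
        self.spec = spec
        self.inc = _DoubleConv(1, cs[0], cpg, rng, dtype)
        self.pools = [nn.MaxPool2() for _ in range(4)]
        self.downs = [_DoubleConv(cs[i], cs[i + 1], cpg, rng, dtype)
                      for i in range(4)]
        self.ups = [nn.ConvTranspose2(cs[i + 1], cs[i], rng, dtype)
                    for i in range(4)]
        self.updc = [_DoubleConv(2 * cs[i], cs[i], cpg, rng, dtype)
                     for i in range(4)]
        self.outc = nn.Conv2d(cs[0], spec.features_per_frame, 1, rng, dtype)
        self.bottleneck_shape: tuple | None = None

    @staticmethod
    def _check_shape(H: int, W: int) -> None:
        if H % 16 or W % 16:
            raise ValueError(
                f"image side must be divisible by 16 (four 2x downsamplings), "
                f"got {H}x{W}")

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, 1, H, W) single-channel frames -> (N, F, H, W) features."""
        self._check_shape(x.shape[2], x.shape[3])
        enc = [self.inc.forward(x)]
        for i in range(4):
            enc.append(self.downs[i].forward(self.pools[i].forward(enc[-1])))
        self.bottleneck_shape = enc[-1].shape
        d = enc[-1]
        self._skip_channels = [e.shape[1] for e in enc[:4]]
        for i in range(3, -1, -1):
            up = self.ups[i].forward(d)
            d = self.updc[i].forward(np.concatenate([up, enc[i]], axis=1))
        return self.outc.forward(d)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dd = self.outc.backward(dy)
        dskips = [None] * 4
        for i in range(4):
            dcat = self.updc[i].backward(dd)
            c = self._skip_channels[i]
            dd = self.ups[i].backward(dcat[:, :c])
            dskips[i] = dcat[:, c:]
        g = dd  # gradient w.r.t. the bottleneck
        for i in range(3, -1, -1):
            g = self.pools[i].backward(self.downs[i].backward(g)) + dskips[i]
        return self.inc.backward(g)


class PointwiseHead(nn.Module):
    """Stack of 1x1 convolutions: every voxel is regressed independently
    from its feature vector.  The hybrid head ends in a scaled sigmoid onto
    the physical parameter ranges; the model-free head is unbounded."""

    def __init__(self, in_channels: int, hidden: tuple = (256, 128, 64),
                 out_channels: int = 5, ranges: ParamRanges | None = None,
                 rng: np.random.Generator | None = None, dtype=np.float64):
        rng = rng or np.random.default_rng()
        widths = (in_channels,) + tuple(hidden)
        layers: list = []
        for cin, cout in zip(widths[:-1], widths[1:]):
            layers += [nn.Conv2d(cin, cout, 1, rng, dtype), nn.ReLU()]
        layers.append(nn.Conv2d(widths[-1], out_channels, 1, rng, dtype))
        if ranges is not None:
            layers.append(_ScaledSigmoid(ranges))
        self.net = nn.Sequential(*layers)

    def forward(self, x):
        return self.net.forward(x)

    def backward(self, dy):
        return self.net.backward(dy)


class KineticLayer:
    """Differentiable map from 2TCM parameter maps to frame images.

    Precomputes the dense time grid, the blood curve on it and the frame
    quadrature matrix; the per-voxel forward cost is two exponential
    convolutions and their frame integrals.  The backward pass uses the exact
    derivative of the discretised convolution with respect to the
    eigenvalues (``d g / d alpha = -(t-weighted convolution)``) and analytic
    chain rules through the macro-rates.  Near-degenerate eigenvalue pairs
    are handled by flooring the discriminant at ``disc_floor``, which keeps
    the amplitudes bounded and the gradients finite.
    """

    def __init__(self, blood: BloodInput, schedule: FrameSchedule,
                 grid_dt: float = DEFAULT_GRID_DT, mode: str = "average",
                 disc_floor: float = 1e-6, dtype=np.float64):
        grid = np.arange(0.0, schedule.ends[-1] + grid_dt / 2, grid_dt)
        if grid[-1] < schedule.ends[-1]:
            grid = np.append(grid, schedule.ends[-1])
        self.dtype = dtype
        self.grid = grid
        self.c0 = blood(grid)
        self.Q = frame_quadrature(grid, schedule, mode=mode).astype(dtype)
        self.wb = self.Q @ self.c0.astype(dtype)
        self.schedule = schedule
        self.disc_floor = disc_floor
        self.n_frames = schedule.n_frames

    def forward(self, params: np.ndarray, need_grad: bool = True) -> np.ndarray:
        """params: (5, V) in order (fv, K1, k2, k3, k4) -> frames (T, V)."""
        p = np.asarray(params, dtype=self.dtype)
        fv, K1, k2, k3, k4 = p
        s = k2 + k3 + k4
        disc2 = s * s - 4.0 * k2 * k4
        disc = np.sqrt(np.maximum(disc2, self.disc_floor ** 2))
        clamped = disc2 < self.disc_floor ** 2
        alpha1 = 0.5 * (s - disc)
        alpha2 = 0.5 * (s + disc)
        u = k3 + k4 - alpha1
        a = K1 * u / disc
        b = K1 - a
        V = p.shape[1]
        alphas = np.concatenate([alpha1, alpha2])
        if need_grad:
            g, h = exp_conv(self.grid, self.c0, alphas, with_t_weight=True)
            self._h = h
        else:
            g = exp_conv(self.grid, self.c0, alphas)
            self._h = None
        F = self.Q @ g  # (T, 2V)
        F1, F2 = F[:, :V], F[:, V:]
        ct = a[None, :] * F1 + b[None, :] * F2
        frames = (1.0 - fv)[None, :] * ct + fv[None, :] * self.wb[:, None]
        self._cache = (p, s, disc, clamped, alpha1, u, a, b, F1, F2, ct)
        return frames

    def backward(self, dframes: np.ndarray) -> np.ndarray:
        """dframes: (T, V) -> gradient w.r.t. params, (5, V)."""
        if self._h is None:
            raise RuntimeError("forward was called with need_grad=False")
        p, s, disc, clamped, alpha1, u, a, b, F1, F2, ct = self._cache
        fv, K1, k2, k3, k4 = p
        V = p.shape[1]
        dX = np.asarray(dframes, dtype=self.dtype)

        dfv = (dX * (self.wb[:, None] - ct)).sum(axis=0)
        dct = dX * (1.0 - fv)[None, :]
        da = (dct * F1).sum(axis=0)
        db = (dct * F2).sum(axis=0)
        dF = np.concatenate([dct * a[None, :], dct * b[None, :]], axis=1)
        dg = self.Q.T @ dF  # (G, 2V)
        dalpha = -(dg * self._h).sum(axis=0)
        dalpha1, dalpha2 = dalpha[:V], dalpha[V:]

        # chain through the macro-rates; s' = 1 for each of k2, k3, k4
        inv = 1.0 / disc
        ddisc_k2 = np.where(clamped, 0.0, (s - 2.0 * k4) * inv)
        ddisc_k3 = np.where(clamped, 0.0, s * inv)
        ddisc_k4 = np.where(clamped, 0.0, (s - 2.0 * k2) * inv)

        dal1_k2 = 0.5 * (1.0 - ddisc_k2)
        dal1_k3 = 0.5 * (1.0 - ddisc_k3)
        dal1_k4 = 0.5 * (1.0 - ddisc_k4)
        dal2_k2 = 0.5 * (1.0 + ddisc_k2)
        dal2_k3 = 0.5 * (1.0 + ddisc_k3)
        dal2_k4 = 0.5 * (1.0 + ddisc_k4)

        du_k2 = -dal1_k2
        du_k3 = 1.0 - dal1_k3
        du_k4 = 1.0 - dal1_k4

        def da_dk(du, ddisc):
            return K1 * (du * disc - u * ddisc) * inv * inv

        da_k2, da_k3, da_k4 = (da_dk(du_k2, ddisc_k2),
                               da_dk(du_k3, ddisc_k3),
                               da_dk(du_k4, ddisc_k4))
        dab = da - db  # since b = K1 - a
        dK1 = da * (u * inv) + db * (1.0 - u * inv)
        dk2 = dab * da_k2 + dalpha1 * dal1_k2 + dalpha2 * dal2_k2
        dk3 = dab * da_k3 + dalpha1 * dal1_k3 + dalpha2 * dal2_k3
        dk4 = dab * da_k4 + dalpha1 * dal1_k4 + dalpha2 * dal2_k4
        return np.stack([dfv, dK1, dk2, dk3, dk4])


class HybridModel(nn.Module):
    """U-Net features -> pointwise parameter head -> kinetic layer.

    ``forward`` maps the 22 input frames to the full predicted series (all
    schedule frames) plus the per-voxel parameter maps; gradients flow from
    the frame loss through the kinetic layer into all network weights.
    """

    def __init__(self, blood: BloodInput, schedule: FrameSchedule,
                 encoder_spec: EncoderSpec = EncoderSpec(),
                 head_hidden: tuple = (256, 128, 64),
                 ranges: ParamRanges = ParamRanges(),
                 grid_dt: float = DEFAULT_GRID_DT,
                 seed: int = 0, dtype=np.float64):
        rng = np.random.default_rng(seed)
        self.dtype = dtype
        self.encoder_spec = encoder_spec
        self.ranges = ranges
        self.unet = UNetFeatureExtractor(encoder_spec, rng, dtype)
        self.head = PointwiseHead(encoder_spec.feature_dim, head_hidden,
                                  5, ranges, rng, dtype)
        self.kinetic = KineticLayer(blood, schedule, grid_dt=grid_dt,
                                    dtype=dtype)
        self.schedule = schedule

    def extract_features(self, frames: np.ndarray) -> np.ndarray:
        """(T_i, H, W) input frames -> (T_i * F, H, W) per-voxel features."""
        T, H, W = frames.shape
        if T != self.encoder_spec.input_frames:
            raise ValueError(
                f"expected {self.encoder_spec.input_frames} input frames, got {T}")
        x = frames[:, None].astype(self.dtype)
        feats = self.unet.forward(x)  # (T, F, H, W)
        return feats.reshape(T * self.encoder_spec.features_per_frame, H, W)

    def predict_params(self, features: np.ndarray) -> np.ndarray:
        """(T_i * F, H, W) feature stack -> (5, H, W) parameter maps."""
        out = self.head.forward(features[None].astype(self.dtype))
        return out[0]

    def forward(self, frames: np.ndarray, need_grad: bool = True):
        T, H, W = frames.shape
        feats = self.extract_features(frames)
        params = self.predict_params(feats)
        pred = self.kinetic.forward(
            params.reshape(5, H * W), need_grad=need_grad)
        self._hw = (H, W)
        return pred.reshape(-1, H, W), params

    def backward(self, dpred: np.ndarray,
                 dparams: np.ndarray | None = None) -> None:
        H, W = self._hw
        dp = self.kinetic.backward(dpred.reshape(-1, H * W)).reshape(5, H, W)
        if dparams is not None:
            dp = dp + dparams
        dfeat = self.head.backward(dp[None].astype(self.dtype))[0]
        F = self.encoder_spec.features_per_frame
        self.unet.backward(
            dfeat.reshape(-1, F, H, W).astype(self.dtype))


class WithoutModelNet(nn.Module):
    """Ablation: identical backbone, pointwise head straight to the target
    frames, no bounded activation and no kinetic layer."""

    def __init__(self, encoder_spec: EncoderSpec = EncoderSpec(),
                 head_hidden: tuple = (256, 128, 64), n_target_frames: int = 6,
                 seed: int = 0, dtype=np.float64):
        rng = np.random.default_rng(seed)
        self.dtype = dtype
        self.encoder_spec = encoder_spec
        self.n_target_frames = n_target_frames
        self.unet = UNetFeatureExtractor(encoder_spec, rng, dtype)
        self.head = PointwiseHead(encoder_spec.feature_dim, head_hidden,
                                  n_target_frames, None, rng, dtype)

    def forward(self, frames: np.ndarray) -> np.ndarray:
        T, H, W = frames.shape
        if T != self.encoder_spec.input_frames:
            raise ValueError(
                f"expected {self.encoder_spec.input_frames} input frames, got {T}")
        feats = self.unet.forward(frames[:, None].astype(self.dtype))
        stack = feats.reshape(
            1, T * self.encoder_spec.features_per_frame, H, W)
        return self.head.forward(stack)[0]

    def backward(self, dpred: np.ndarray) -> None:
        H, W = dpred.shape[1:]
        dfeat = self.head.backward(dpred[None].astype(self.dtype))[0]
        F = self.encoder_spec.features_per_frame
        self.unet.backward(dfeat.reshape(-1, F, H, W))
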