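"""Image-quality and agreement metrics for SUV frames and Ki maps.

Thin, convention-pinning wrappers: SSIM and PSNR delegate to scikit-image
with the data range anchored to the *reference* image; NMI is the symmetric
normalised mutual information ``2 I(a;b) / (H(a) + H(b))`` over a 64-bin
joint histogram; Bland-Altman returns the mean difference and the 95% limits
of agreement (mean +/- 1.96 sd, sample sd).
"""

from __future__ import annotations

import numpy as np
from skimage.metrics import peak_signal_noise_ratio, structural_similarity

__all__ = ["ssim", "psnr", "nmi", "rmse", "bland_altman", "metric_report",
           "percent_improvement"]


def _check_pair(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("metrics require finite inputs")
    return a, b


def _data_range(ref: np.ndarray) -> float:
    r = float(ref.max() - ref.min())
    return r if r > 0 else 1.0


def ssim(a: np.ndarray, ref: np.ndarray) -> float:
    """Structural similarity of ``a`` against reference ``ref`` (7x7 uniform
    window, K1=0.01, K2=0.03, data range from the reference)."""
    a, ref = _check_pair(a, ref)
    return float(structural_similarity(a, ref, data_range=_data_range(ref)))


def psnr(a: np.ndarray, ref: np.ndarray) -> float:
    """Peak SNR in dB, data range from the reference; inf for identical."""
    a, ref = _check_pair(a, ref)
    if np.array_equal(a, ref):
        return float("inf")
    return float(peak_signal_noise_ratio(ref, a, data_range=_data_range(ref)))


def rmse(a: np.ndarray, ref: np.ndarray) -> float:
    a, ref = _check_pair(a, ref)
    return float(np.sqrt(np.mean((a - ref) ** 2)))


def nmi(a: np.ndarray, ref: np.ndarray, bins: int = 64) -> float:
    """Normalised mutual information ``2 I(a;b) / (H(a)+H(b))``.

    Joint histogram over ``bins`` equal-width bins spanning the union range
    of both images; returns 1 only when the histograms are perfectly
    co-informative (e.g. identical images).
    """
    a, ref = _check_pair(a, ref)
    lo = min(a.min(), ref.min())
    hi = max(a.max(), ref.max())
    if hi == lo:
        hi = lo + 1.0
    joint, _, _ = np.histogram2d(a.ravel(), ref.ravel(), bins=bins,
                                 range=[[lo, hi], [lo, hi]])
    p = joint / joint.sum()
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)

    def entropy(q):
        q = q[q > 0]
        return -np.sum(q * np.log(q))

    ha, hb = entropy(pa), entropy(pb)
    hab = entropy(p.ravel())
    mi = ha + hb - hab
    if ha + hb == 0:
        return 1.0
    return float(2.0 * mi / (ha + hb))


def bland_altman(a, b):
    """Agreement of paired samples: returns (mean difference, lower limit of
    agreement, upper limit), LoA = mean +/- 1.96 sd (n-1 denominator)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("Bland-Altman requires finite samples")
    d = a - b
    m = float(d.mean())
    sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
    return m, m - 1.96 * sd, m + 1.96 * sd


def metric_report(a: np.ndarray, ref: np.ndarray,
                  roi: np.ndarray | None = None) -> dict:
    """All scalar metrics for one image pair, plus Bland-Altman over a
    boolean ROI (whole image if omitted)."""
    out = {
        "ssim": ssim(a, ref),
        "psnr": psnr(a, ref),
        "nmi": nmi(a, ref),
        "rmse": rmse(a, ref),
    }
    sel = (np.asarray(roi, bool) if roi is not None
           else np.ones(np.shape(a), bool))
    mean, lo, hi = bland_altman(np.asarray(a)[sel], np.asarray(ref)[sel])
    out["bland_altman"] = {"mean": mean, "loa_low": lo, "loa_high": hi}
    return out


def percent_improvement(method: float, baseline: float) -> float:
    """(method - baseline) / baseline, in percent."""
    if baseline == 0:
        raise ValueError("baseline metric is zero")
    return 100.0 * (method - baseline) / baseline
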