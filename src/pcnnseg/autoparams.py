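"""Automatic parameter setting from image statistics.

The SPCNN's neuron parameters are derived from three statistics of the
normalized image: the population standard deviation σ, the maximum
intensity Smax, and a reference intensity S′ (the Otsu threshold).  The
formulas are designed so that, from a zero initial state, every neuron
pulses at iteration 1, none at iteration 2, and thereafter the threshold
sweeps downward through the intensity range, peeling off one intensity
stratum per iteration.

The variable-step model adds a sinusoidal step-size schedule
ST(t) = 0.5 sin(w t + φ) + 0.5 whose angular frequency w = log(1/σ) is tied
to the same image statistic, leaving the phase φ as the single supervised
parameter.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .dynamics import DEFAULT_KERNEL, ModelParams

__all__ = [
    "ImageStats",
    "normalize_image",
    "estimate_stats",
    "spcnn_auto_params",
    "compute_w",
    "st_schedule",
    "params_to_json",
    "params_from_json",
]


@dataclass(frozen=True)
class ImageStats:
    """σ, Smax and S′ of a normalized image (all on the [0, 1] scale)."""

    sigma: float
    smax: float
    sprime: float

    def __post_init__(self) -> None:
        if not (0.0 < self.sigma < 1.0):
            raise ValueError(f"sigma must lie in (0, 1), got {self.sigma}")
        if not (0.0 < self.smax <= 1.0):
            raise ValueError(f"smax must lie in (0, 1], got {self.smax}")
        if not (0.0 < self.sprime <= self.smax):
            raise ValueError(f"sprime must lie in (0, smax], got {self.sprime}")


def normalize_image(image: np.ndarray) -> np.ndarray:
    """Map an image to float64 intensities in [0, 1].

    Integer images are divided by their container maximum (255 for 8-bit,
    65535 for 16-bit); float images must already lie in [0, 1].
    """
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError(f"expected a single-channel 2-D image, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        if info.max <= 0:
            raise ValueError(f"unsupported integer dtype {arr.dtype}")
        return arr.astype(float) / float(info.max)
    arr = arr.astype(float)
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("float images must be pre-normalized to [0, 1]")
    return arr


def estimate_stats(image: np.ndarray) -> ImageStats:
    """Estimate (σ, Smax, S′) from an image.

    σ is the population standard deviation of the normalized intensities;
    Smax their maximum; S′ the Otsu threshold of the normalized image.
    A constant image has σ = 0 and no defined automatic parameters.
    """
    s = normalize_image(image)
    sigma = float(np.std(s))
    if sigma == 0.0:
        raise ValueError("sigma = 0: automatic parameters undefined for a constant image")
    smax = float(np.max(s))
    sprime = float(threshold_otsu(s))
    # Otsu of a strongly bottom-heavy histogram can sit at/below 0; keep S'
    # inside (0, smax] so the ratio Smax/S' stays finite.
    sprime = min(max(sprime, 1e-6), smax)
    return ImageStats(sigma=sigma, smax=smax, sprime=sprime)


def spcnn_auto_params(stats: ImageStats, sprime: float | None = None) -> ModelParams:
    """SPCNN parameters from image statistics.

    aF = log(1/σ)
    VL = 1
    β  = (Smax / S′) / (6 VL)
    VE = e^{-aF} + 1 + 6 β VL
    aE = log( VE / (Smax (1 − e^{-3aF}) / (1 − e^{-aF}) + 6 β VL e^{-aF}) )

    The constant 6 is the total weight of the default 3x3 kernel; the
    formulas presuppose that kernel.  ``sprime`` overrides the S′ stored in
    ``stats`` (e.g. when a domain-specific reference intensity is known).
    """
    if not (0.0 < stats.sigma < 1.0):
        raise ValueError("automatic parameters need 0 < sigma < 1 (aF = log(1/sigma) > 0)")
    sp = stats.sprime if sprime is None else float(sprime)
    if not (0.0 < sp <= stats.smax):
        raise ValueError(f"sprime must lie in (0, smax], got {sp}")
    af = math.log(1.0 / stats.sigma)
    vl = 1.0
    beta = (stats.smax / sp) / (6.0 * vl)
    q = math.exp(-af)
    ve = q + 1.0 + 6.0 * beta * vl
    denom = stats.smax * (1.0 - q**3) / (1.0 - q) + 6.0 * beta * vl * q
    ae = math.log(ve / denom)
    if not (math.isfinite(ae) and ae > 0):
        raise ValueError(f"derived aE = {ae} is not positive; stats outside the supported regime")
    return ModelParams(af=af, ae=ae, ve=ve, beta=beta, vl=vl,
                       kernel_w=DEFAULT_KERNEL.copy(), kernel_m=DEFAULT_KERNEL.copy())


def compute_w(sigma: float) -> float:
    """Angular frequency of the step schedule: w = log(1/σ), natural log."""
    if not (0.0 < sigma < 1.0):
        raise ValueError(f"sigma must lie in (0, 1), got {sigma}")
    return math.log(1.0 / sigma)


def st_schedule(w: float, phi: float, t: int) -> float:
    """Closed-form sinusoidal step size ST(t) = 0.5 sin(w t + φ) + 0.5.

    Bounded in [0, 1] for all real inputs; ``t`` is the 1-based iteration
    index.
    """
    if t < 1 or int(t) != t:
        raise ValueError("t must be a positive integer iteration index")
    return 0.5 * math.sin(w * t + phi) + 0.5


def params_to_json(params: ModelParams, path=None) -> str:
    """Serialize parameters to JSON (optionally writing to ``path``)."""
    text = json.dumps(params.to_dict(), indent=2, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def params_from_json(source) -> ModelParams:
    """Load parameters from a JSON string or file path."""
    if isinstance(source, str) and source.lstrip().startswith("{"):
        d = json.loads(source)
    else:
        with open(source) as fh:
            d = json.load(fh)
    return ModelParams.from_dict(d)
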