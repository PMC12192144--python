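"""Lattice update kernels for pulse-coupled neural network (PCNN) variants.

A PCNN is a 2-D lattice of laterally coupled leaky-integrator neurons, one
per pixel.  Each neuron accumulates the external stimulus ``S`` (the pixel
intensity) together with pulses received from its 8-neighborhood into an
internal activity ``U``, and emits a binary pulse ``Y = 1`` whenever ``U``
strictly exceeds a dynamic threshold ``E``.  The threshold decays
exponentially between pulses and jumps by ``VE`` after each pulse (a
refractory mechanism), so neurons with similar stimuli tend to pulse in the
same iteration — the synchronous firing that makes the lattice cluster
image regions.

Four update kernels are provided:

``pcnn_iterate``
    the classic feeding/linking neuron,
``spcnn_iterate``
    the simplified PCNN (single internal-activity recurrence),
``varstep_iterate``
    the second-order recurrence in which the discrete time increment
    ("step size", ST) may change every iteration.  With ST fixed at 1 it
    reproduces the SPCNN exactly; with a fixed decimal ST it realizes the
    non-integer-step model.

All arithmetic is double precision.  Pulses are stored as float arrays with
values in {0.0, 1.0} so they can enter convolutions directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import convolve2d

__all__ = [
    "DEFAULT_KERNEL",
    "ModelParams",
    "LatticeState",
    "StepSchedule",
    "ST_FLOOR",
    "neighborhood_sum",
    "pcnn_iterate",
    "spcnn_iterate",
    "varstep_iterate",
]

#: Default linking/feeding kernel.  Its total weight is 6, which is the
#: constant that appears in the automatic parameter formulas (the "6βVL"
#: terms), so those formulas presuppose exactly this kernel.
DEFAULT_KERNEL = np.array(
    [[0.5, 1.0, 0.5], [1.0, 0.0, 1.0], [0.5, 1.0, 0.5]], dtype=float
)

#: Smallest step size the scheduler will emit.  A step of exactly zero would
#: freeze the lattice clock; the floor is far below any fidelity tolerance.
ST_FLOOR = 1e-12


def _as_kernel(k: np.ndarray) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    if k.shape != (3, 3):
        raise ValueError(f"kernel must be 3x3, got shape {k.shape}")
    if k[1, 1] != 0.0:
        raise ValueError("kernel center weight must be 0 (a neuron is not its own neighbor)")
    return k


@dataclass
class ModelParams:
    """Neuron parameters shared by all model variants.

    Decay exponents (``af``, ``al``, ``ae``) are dimensionless and must be
    positive; amplification coefficients (``vf``, ``vl``, ``ve``) must be
    nonnegative.  ``beta`` is the linking strength.  ``kernel_w`` and
    ``kernel_m`` are the 3x3 linking and feeding kernels (zero center).
    """

    af: float
    ae: float
    ve: float
    beta: float
    vl: float = 1.0
    al: float = 1.0
    vf: float = 0.0
    kernel_w: np.ndarray = field(default_factory=lambda: DEFAULT_KERNEL.copy())
    kernel_m: np.ndarray = field(default_factory=lambda: DEFAULT_KERNEL.copy())

    def __post_init__(self) -> None:
        for name in ("af", "al", "ae"):
            if getattr(self, name) <= 0:
                raise ValueError(f"decay exponent {name} must be > 0")
        for name in ("vf", "vl", "ve"):
            if getattr(self, name) < 0:
                raise ValueError(f"amplification coefficient {name} must be >= 0")
        self.kernel_w = _as_kernel(self.kernel_w)
        self.kernel_m = _as_kernel(self.kernel_m)

    @classmethod
    def classic_defaults(cls) -> "ModelParams":
        """Conventional hand-set parameters for the classic PCNN."""
        return cls(af=0.1, al=1.0, ae=0.5, vf=0.5, vl=1.0, ve=20.0, beta=0.1)

    def to_dict(self) -> dict:
        return {
            "af": self.af, "al": self.al, "ae": self.ae,
            "vf": self.vf, "vl": self.vl, "ve": self.ve,
            "beta": self.beta,
            "kernel_w": self.kernel_w.tolist(),
            "kernel_m": self.kernel_m.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        d = dict(d)
        d["kernel_w"] = np.asarray(d["kernel_w"], dtype=float)
        d["kernel_m"] = np.asarray(d["kernel_m"], dtype=float)
        return cls(**d)


@dataclass
class LatticeState:
    """Per-pixel fields of the lattice plus one- and two-step histories.

    ``u``/``y`` are the most recent internal activity and pulse field;
    ``u_prev``/``y_prev`` are one step further back (needed by the
    second-order variable-step recurrence).  ``n`` counts completed
    iterations.
    """

    f: np.ndarray
    l: np.ndarray
    u: np.ndarray
    u_prev: np.ndarray
    e: np.ndarray
    y: np.ndarray
    y_prev: np.ndarray
    n: int = 0

    @classmethod
    def zeros(cls, shape: tuple[int, int]) -> "LatticeState":
        z = lambda: np.zeros(shape, dtype=float)
        return cls(f=z(), l=z(), u=z(), u_prev=z(), e=z(), y=z(), y_prev=z(), n=0)

    @classmethod
    def from_stimulus(cls, s: np.ndarray) -> "LatticeState":
        """Zero state with the internal activity preloaded to the stimulus."""
        st = cls.zeros(np.asarray(s).shape)
        st.u = np.asarray(s, dtype=float).copy()
        return st

    def _check(self, s: np.ndarray) -> None:
        if self.u.shape != np.asarray(s).shape:
            raise ValueError(
                f"stimulus shape {np.asarray(s).shape} does not match state shape {self.u.shape}"
            )

    def to_npz(self, path) -> None:
        np.savez(path, f=self.f, l=self.l, u=self.u, u_prev=self.u_prev,
                 e=self.e, y=self.y, y_prev=self.y_prev, n=self.n)


@dataclass
class StepSchedule:
    """How the step size ST is chosen at each iteration.

    Modes:

    ``fixed``
        constant ``st_fixed`` in (0, 1] (1.0 reproduces the SPCNN).
    ``sinusoidal``
        ST(t) = 0.5*sin(w*t + phi) + 0.5, the bounded oscillating schedule;
        ``w`` is the angular frequency (set from image statistics) and
        ``phi`` the phase, the single supervised parameter, constrained to
        [0, pi/w].
    ``explicit``
        a caller-supplied per-iteration sequence (random-search mode).
    """

    mode: str
    st_fixed: float | None = None
    w: float | None = None
    phi: float | None = None
    st_sequence: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if self.mode == "fixed":
            if self.st_fixed is None or not (0.0 < self.st_fixed <= 1.0):
                raise ValueError("fixed mode requires st_fixed in (0, 1]")
        elif self.mode == "sinusoidal":
            if self.w is None or self.w <= 0:
                raise ValueError("sinusoidal mode requires w > 0")
            if self.phi is None:
                self.phi = 0.0
            if not (0.0 <= self.phi <= math.pi / self.w):
                raise ValueError(f"phi must lie in [0, pi/w] = [0, {math.pi / self.w:.6g}]")
        elif self.mode == "explicit":
            if self.st_sequence is None or len(self.st_sequence) == 0:
                raise ValueError("explicit mode requires a nonempty st_sequence")
            seq = np.asarray(self.st_sequence, dtype=float)
            if np.any(seq < 0) or np.any(seq > 1):
                raise ValueError("explicit ST values must lie in [0, 1]")
            self.st_sequence = seq
        else:
            raise ValueError(f"unknown schedule mode {self.mode!r}")

    @classmethod
    def fixed(cls, st: float) -> "StepSchedule":
        return cls(mode="fixed", st_fixed=float(st))

    @classmethod
    def sinusoidal(cls, w: float, phi: float = 0.0) -> "StepSchedule":
        return cls(mode="sinusoidal", w=float(w), phi=float(phi))

    @classmethod
    def explicit(cls, seq: Sequence[float]) -> "StepSchedule":
        return cls(mode="explicit", st_sequence=seq)

    def st_at(self, t: int) -> float:
        """Step size for iteration ``t`` (1-based), floored at ``ST_FLOOR``."""
        if t < 1:
            raise ValueError("iteration index t must be >= 1")
        if self.mode == "fixed":
            st = self.st_fixed
        elif self.mode == "sinusoidal":
            st = 0.5 * math.sin(self.w * t + self.phi) + 0.5
        else:
            if t > len(self.st_sequence):
                raise ValueError(f"explicit schedule exhausted at t={t}")
            st = float(self.st_sequence[t - 1])
        return max(st, ST_FLOOR)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "st_fixed": self.st_fixed,
            "w": self.w,
            "phi": self.phi,
            "st_sequence": None if self.st_sequence is None else list(map(float, self.st_sequence)),
        }


def neighborhood_sum(y: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Weighted sum of 8-neighborhood pulses, zero-padded at the border.

    This is the ΣW·Y coupling term of every model variant.  Out-of-lattice
    neighbors contribute 0 (they never fired).  True convolution semantics:
    a single firing pixel deposits the mirrored kernel onto its neighbors.
    """
    kernel = _as_kernel(kernel)
    return convolve2d(np.asarray(y, dtype=float), kernel, mode="same",
                      boundary="fill", fillvalue=0.0)


def pcnn_iterate(state: LatticeState, s: np.ndarray, p: ModelParams) -> LatticeState:
    """One step of the classic feeding/linking PCNN neuron.

    L[n] = e^{-aL} L[n-1] + VL ΣW Y[n-1]
    F[n] = e^{-aF} F[n-1] + S + VF ΣM Y[n-1]
    U[n] = F[n] (1 + β L[n])
    Y[n] = 1 if U[n] > e^{-aE} E[n-1] (strict), else 0
    E[n] = e^{-aE} E[n-1] + VE Y[n]
    """
    state._check(s)
    s = np.asarray(s, dtype=float)
    l = math.exp(-p.al) * state.l + p.vl * neighborhood_sum(state.y, p.kernel_w)
    f = math.exp(-p.af) * state.f + s + p.vf * neighborhood_sum(state.y, p.kernel_m)
    u = f * (1.0 + p.beta * l)
    e_dec = math.exp(-p.ae) * state.e
    y = (u > e_dec).astype(float)
    e = e_dec + p.ve * y
    return LatticeState(f=f, l=l, u=u, u_prev=state.u, e=e, y=y,
                        y_prev=state.y, n=state.n + 1)


def spcnn_iterate(state: LatticeState, s: np.ndarray, p: ModelParams) -> LatticeState:
    """One step of the simplified PCNN (first-order internal activity).

    U[n] = S (1 + β VL ΣW Y[n-1]) + e^{-aF} U[n-1]
    E[n] = e^{-aE} E[n-1] + VE Y[n-1]
    Y[n] = 1 if U[n] > E[n] (strict), else 0
    """
    state._check(s)
    s = np.asarray(s, dtype=float)
    coupling = neighborhood_sum(state.y, p.kernel_w)
    u = s * (1.0 + p.beta * p.vl * coupling) + math.exp(-p.af) * state.u
    e = math.exp(-p.ae) * state.e + p.ve * state.y
    y = (u > e).astype(float)
    return LatticeState(f=state.f, l=state.l, u=u, u_prev=state.u, e=e, y=y,
                        y_prev=state.y, n=state.n + 1)


def varstep_iterate(state: LatticeState, s: np.ndarray, p: ModelParams,
                    st: float) -> LatticeState:
    """One step of the variable-step-size second-order recurrence.

    With q = e^{-aF·ST},

    U[n] = S β VL (ΣW Y[n-1] − ΣW Y[n-2]) + (1+q) U[n-1] − q U[n-2]
    E[n] = e^{-aE·ST} E[n-1] + VE Y[n-1]
    Y[n] = 1 if U[n] > E[n] (strict), else 0

    The first iteration (no two-step history yet) runs the first-order
    bootstrap U[1] = S (1 + β VL ΣW Y[0]) + q U[0].  The membrane and
    threshold clocks share the step: both decays are scaled by ST.
    """
    state._check(s)
    if not (0.0 < st <= 1.0):
        raise ValueError(f"step size ST must lie in (0, 1], got {st}")
    if state.u_prev is None or state.y_prev is None:
        raise ValueError("varstep_iterate requires populated state histories")
    s = np.asarray(s, dtype=float)
    q = math.exp(-p.af * st)
    if state.n == 0:
        u = s * (1.0 + p.beta * p.vl * neighborhood_sum(state.y, p.kernel_w)) + q * state.u
    else:
        dcoup = (neighborhood_sum(state.y, p.kernel_w)
                 - neighborhood_sum(state.y_prev, p.kernel_w))
        u = s * p.beta * p.vl * dcoup + (1.0 + q) * state.u - q * state.u_prev
    e = math.exp(-p.ae * st) * state.e + p.ve * state.y
    y = (u > e).astype(float)
    return LatticeState(f=state.f, l=state.l, u=u, u_prev=state.u, e=e, y=y,
                        y_prev=state.y, n=state.n + 1)
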