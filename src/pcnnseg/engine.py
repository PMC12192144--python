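"""End-to-end segmentation: run a model, record firing times, derive groups.

The segmentation output of a PCNN is read off the *firing-time map*: the
iteration at which each neuron first pulses.  Because the dynamic threshold
sweeps downward through the intensity range, brighter pixels fire earlier,
and pixels sharing a first-fire iteration form one segmentation group.

With the zero initial state every stimulated neuron pulses at iteration 1
(the threshold starts at 0); that synchronous calibration flash carries no
contrast information, so firing maps are recorded from iteration 2 by
default (``record_from``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autoparams import compute_w, estimate_stats, spcnn_auto_params
from .dynamics import (LatticeState, ModelParams, StepSchedule, pcnn_iterate,
                       spcnn_iterate, varstep_iterate)

__all__ = [
    "FiringMap",
    "SegmentationResult",
    "run_segmentation",
    "groups_from_firing",
    "binarize_from_firing",
    "binarization_threshold",
    "false_color_map",
    "segment_image",
    "MODELS",
    "PALETTE",
]

MODELS = ("pcnn", "spcnn", "fixedstep", "varstep")

#: Cool-to-warm palette for firing order: blue, light blue, green, yellow,
#: orange, red.  The earlier a neuron fires, the cooler its color.
PALETTE = np.array(
    [[0, 0, 255], [0, 255, 255], [0, 255, 0],
     [255, 255, 0], [255, 165, 0], [255, 0, 0]], dtype=float
)


@dataclass
class FiringMap:
    """Per-pixel firing record of one segmentation run.

    ``first_fire`` holds the iteration index of each pixel's first recorded
    pulse (0 = never fired); ``fire_count`` the total recorded pulses.
    ``second_fire`` holds the iteration of the second recorded pulse
    (0 = none), which delimits the first firing cycle.  ``st_sequence`` is
    the step size actually used at each iteration (None for the classic
    model, which has no step-size notion).
    """

    first_fire: np.ndarray
    fire_count: np.ndarray
    nmax: int
    model: str
    record_from: int = 2
    st_sequence: list[float] | None = None
    second_fire: np.ndarray | None = None

    @property
    def earliest_refire(self) -> int:
        """Iteration of the earliest second pulse (0 if no pixel refired)."""
        if self.second_fire is None:
            return 0
        refired = self.second_fire[self.second_fire > 0]
        return int(refired.min()) if refired.size else 0


@dataclass
class SegmentationResult:
    """Group decomposition of a firing map.

    ``labels`` assigns consecutive integer group ids from 1 in order of
    ascending first-fire iteration (0 = never fired).  ``per_group_masks``
    partition the fired region.  ``binary_mask`` is filled by
    ``segment_image`` (it needs the stimulus); None otherwise.
    """

    labels: np.ndarray
    n_groups: int
    per_group_masks: list[np.ndarray]
    group_fire_times: list[int]
    binary_mask: np.ndarray | None = None
    run_log: dict = field(default_factory=dict)


def _resolve_schedule(model: str, schedule: StepSchedule | None) -> StepSchedule | None:
    if model == "pcnn":
        return None
    if model == "spcnn":
        if schedule is not None and not (schedule.mode == "fixed" and schedule.st_fixed == 1.0):
            raise ValueError("spcnn admits no schedule (its step size is identically 1)")
        return StepSchedule.fixed(1.0)
    if model == "fixedstep":
        if schedule is None or schedule.mode != "fixed":
            raise ValueError("fixedstep requires a fixed-mode StepSchedule")
        return schedule
    if model == "varstep":
        if schedule is None or schedule.mode not in ("sinusoidal", "explicit"):
            raise ValueError("varstep requires a sinusoidal or explicit StepSchedule")
        return schedule
    raise ValueError(f"unknown model {model!r}; choose one of {MODELS}")


def run_segmentation(s: np.ndarray, model: str, params: ModelParams,
                     schedule: StepSchedule | None = None, nmax: int = 100,
                     record_from: int = 2, u0: str = "zero") -> FiringMap:
    """Iterate the selected kernel ``nmax`` times and record firing times.

    ``model`` is one of ``pcnn | spcnn | fixedstep | varstep``; the schedule
    must match the model (spcnn and pcnn take none).  ``u0="stimulus"``
    preloads the internal activity with the image before the first
    iteration; the default zero state makes all four models comparable from
    identical initial conditions.  Deterministic: identical inputs yield a
    bit-identical map.
    """
    if nmax < 1:
        raise ValueError("nmax must be >= 1")
    s = np.asarray(s, dtype=float)
    sched = _resolve_schedule(model, schedule)
    if u0 == "zero":
        state = LatticeState.zeros(s.shape)
    elif u0 == "stimulus":
        state = LatticeState.from_stimulus(s)
    else:
        raise ValueError("u0 must be 'zero' or 'stimulus'")
    first = np.zeros(s.shape, dtype=np.int32)
    second = np.zeros(s.shape, dtype=np.int32)
    count = np.zeros(s.shape, dtype=np.int32)
    st_log: list[float] = []
    for n in range(1, nmax + 1):
        if model == "pcnn":
            state = pcnn_iterate(state, s, params)
        elif model == "spcnn":
            state = spcnn_iterate(state, s, params)
            st_log.append(1.0)
        else:
            st = sched.st_at(n)
            state = varstep_iterate(state, s, params, st)
            st_log.append(st)
        if n >= record_from:
            fired = state.y > 0
            first = np.where(fired & (first == 0), n, first)
            second = np.where(fired & (count == 1) & (second == 0), n, second)
            count += fired
    return FiringMap(first_fire=first, fire_count=count, nmax=nmax, model=model,
                     record_from=record_from,
                     st_sequence=st_log if st_log else None, second_fire=second)


def groups_from_firing(fmap: FiringMap, first_cycle_only: bool = False) -> SegmentationResult:
    """Partition fired pixels into groups by first-fire iteration.

    Groups are the equivalence classes of the first-pulse iteration, ordered
    by ascending fire time (group 1 fired earliest).  Each pixel contributes
    only its first pulse, so later periodic re-firing cannot merge classes.
    With ``first_cycle_only=True`` only fire times strictly before the
    earliest second pulse found anywhere on the lattice form their own
    groups; later first-firers are merged into the final group (logged).
    """
    first = fmap.first_fire
    if not np.any(first > 0):
        raise ValueError("no pixel fired; increase Nmax or check threshold init")
    values = sorted(int(v) for v in np.unique(first[first > 0]))
    merged = 0
    if first_cycle_only:
        cycle_end = fmap.earliest_refire
        if cycle_end > 0:
            kept = [v for v in values if v < cycle_end]
            if kept:
                merged = len(values) - len(kept)
                values = kept
    labels = np.zeros(first.shape, dtype=np.int32)
    masks: list[np.ndarray] = []
    for gid, v in enumerate(values, start=1):
        if gid == len(values) and (first_cycle_only and merged):
            m = (first >= v)
        else:
            m = (first == v)
        labels[m] = gid
        masks.append(m)
    return SegmentationResult(
        labels=labels, n_groups=len(values), per_group_masks=masks,
        group_fire_times=values,
        run_log={
            "model": fmap.model, "nmax": fmap.nmax, "record_from": fmap.record_from,
            "st_sequence": fmap.st_sequence, "group_fire_times": values,
            "group_sizes": [int(m.sum()) for m in masks],
            "groups_merged_beyond_first_cycle": merged,
        },
    )


def binarization_threshold(fmap: FiringMap, s: np.ndarray) -> tuple[float, bool]:
    """Gray threshold between the two most populous firing groups.

    Takes the two groups covering the most pixels (ties favor the earlier
    group), reads each group's gray range [min, max] from the stimulus, and
    places the threshold at the midpoint of the gap between the ranges.
    When the ranges overlap (noisy images) it falls back to the midpoint of
    the two group medians; the second return value flags that fallback.
    """
    res = groups_from_firing(fmap)
    if res.n_groups < 2:
        raise ValueError("binarization needs at least 2 firing groups")
    s = np.asarray(s, dtype=float)
    sizes = [m.sum() for m in res.per_group_masks]
    order = sorted(range(res.n_groups), key=lambda k: (-sizes[k], k))
    a, b = order[0], order[1]
    va = s[res.per_group_masks[a]]
    vb = s[res.per_group_masks[b]]
    if np.median(va) > np.median(vb):
        va, vb = vb, va  # va = darker group
    if va.max() < vb.min():
        return 0.5 * (float(va.max()) + float(vb.min())), False
    return 0.5 * (float(np.median(va)) + float(np.median(vb))), True


def binarize_from_firing(fmap: FiringMap, s: np.ndarray,
                         polarity: str = "bright") -> np.ndarray:
    """Binary mask from the gray gap between the two largest firing groups.

    ``polarity="bright"`` (default) marks pixels above the threshold as
    foreground; ``"dark"`` marks pixels below it.
    """
    thr, _ = binarization_threshold(fmap, s)
    s = np.asarray(s, dtype=float)
    if polarity == "bright":
        return s > thr
    if polarity == "dark":
        return s < thr
    raise ValueError("polarity must be 'bright' or 'dark'")


def false_color_map(fmap: FiringMap) -> np.ndarray:
    """False-color rendering of firing order (earlier = cooler).

    Groups are mapped in ascending fire time onto the blue → light blue →
    green → yellow → orange → red palette (endpoints when only two groups,
    the exact six colors for six groups, linear RGB interpolation beyond).
    Never-fired pixels are black.  Returns an (H, W, 3) uint8 image.
    """
    first = fmap.first_fire
    out = np.zeros(first.shape + (3,), dtype=np.uint8)
    values = sorted(int(v) for v in np.unique(first[first > 0]))
    if not values:
        return out
    n = len(values)
    anchors = np.linspace(0.0, 1.0, len(PALETTE))
    for k, v in enumerate(values):
        pos = 0.0 if n == 1 else k / (n - 1)
        rgb = np.array([np.interp(pos, anchors, PALETTE[:, c]) for c in range(3)])
        out[first == v] = np.round(rgb).astype(np.uint8)
    return out


def segment_image(image: np.ndarray, model: str = "spcnn",
                  params: ModelParams | None = None,
                  schedule: StepSchedule | None = None,
                  st: float | None = None, w: float | None = None,
                  phi: float = 0.0, st_sequence=None, nmax: int = 100,
                  polarity: str = "bright", record_from: int = 2,
                  u0: str = "zero") -> tuple[SegmentationResult, FiringMap]:
    """Convenience wrapper: normalize, derive parameters, run, and group.

    Parameters default to the automatic setting (classic defaults for
    ``pcnn``).  For ``fixedstep`` pass ``st``; for ``varstep`` either a
    full ``schedule``, an explicit ``st_sequence``, or ``phi`` (+ optionally
    ``w``; by default w = log(1/σ) of the image).  The returned result has
    ``binary_mask`` filled whenever at least two groups emerged.
    """
    from .autoparams import normalize_image

    s = normalize_image(image)
    if params is None:
        if model == "pcnn":
            params = ModelParams.classic_defaults()
        else:
            params = spcnn_auto_params(estimate_stats(s))
    if schedule is None:
        if model == "fixedstep":
            if st is None:
                raise ValueError("fixedstep requires st")
            schedule = StepSchedule.fixed(st)
        elif model == "varstep":
            if st_sequence is not None:
                schedule = StepSchedule.explicit(st_sequence)
            else:
                if w is None:
                    w = compute_w(estimate_stats(s).sigma)
                schedule = StepSchedule.sinusoidal(w, phi)
    fmap = run_segmentation(s, model, params, schedule, nmax=nmax,
                            record_from=record_from, u0=u0)
    res = groups_from_firing(fmap)
    if res.n_groups >= 2:
        thr, fallback = binarization_threshold(fmap, s)
        res.binary_mask = binarize_from_firing(fmap, s, polarity=polarity)
        res.run_log["binarization_threshold"] = thr
        res.run_log["binarization_fallback"] = fallback
        res.run_log["polarity"] = polarity
    res.run_log["params"] = params.to_dict()
    return res, fmap
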