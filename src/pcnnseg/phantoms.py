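"""Synthetic grayscale phantoms with exact ground-truth masks.

The phantoms stand in for benchmark photographs: piecewise-constant images
whose regions have controlled mean intensities, so the intensity statistics
(σ, Smax, Otsu threshold) that drive the automatic parameters are known in
closed form and every region mask is pixel-exact.  Region boundaries are
axis-aligned bands, disks, or Voronoi blobs with no anti-aliasing, which
keeps IoU targets crisp.

Noise, when wanted, is additive zero-mean Gaussian on the normalized
intensity scale, clipped back to [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Phantom",
    "make_multilevel_phantom",
    "add_gaussian_noise",
    "two_band_phantom",
    "four_level_phantom",
    "FOUR_LEVEL_GRAY_LEVELS",
]

#: Gray levels of the canonical four-level recovery phantom.  Geometric
#: spacing (ratio 1/2): the automatic threshold decays by a constant factor
#: e^{-aE} per iteration, so consecutive levels occupy consecutive distinct
#: firing iterations when their ratio falls between e^{-2aE} and e^{-aE}
#: (aE ≈ 0.5..0.7 for these statistics).  With a monotone band layout every
#: region touches only the adjacent gray levels, so the one-iteration
#: coupling boost a freshly fired band gives its darker neighbor lands
#: exactly on that neighbor's own firing iteration and region masks are
#: recovered pixel-exactly.
FOUR_LEVEL_GRAY_LEVELS = (0.1, 0.2, 0.4, 0.8)


@dataclass
class Phantom:
    """A piecewise-constant test image with its generating truth.

    ``masks`` partition the pixel grid (pairwise disjoint, jointly
    exhaustive); ``gray_levels[k]`` is the declared mean intensity of region
    ``k``; ``sigma_target`` is the population std of the clean image.
    """

    image: np.ndarray
    masks: list[np.ndarray]
    gray_levels: list[float]
    sigma_target: float
    shape_style: str = "bands"
    seed: int | None = None

    @property
    def n_regions(self) -> int:
        return len(self.masks)

    def binary_truth(self, cutoff: float | None = None) -> np.ndarray:
        """Foreground mask: union of regions brighter than ``cutoff``.

        Default cutoff is the midpoint of the full gray-level range, so the
        brightest stratum (or strata) forms the foreground.
        """
        levels = np.asarray(self.gray_levels, dtype=float)
        if cutoff is None:
            cutoff = 0.5 * (levels.min() + levels.max())
        fg = np.zeros(self.image.shape, dtype=bool)
        for g, m in zip(levels, self.masks):
            if g > cutoff:
                fg |= m
        return fg

    def save(self, outdir, bit_depth: int = 8) -> dict:
        """Write image (PNG), per-region 0/255 masks (PNG) and a JSON sidecar."""
        import imageio.v3 as iio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if bit_depth == 8:
            img = np.clip(np.round(self.image * 255), 0, 255).astype(np.uint8)
        elif bit_depth == 16:
            img = np.clip(np.round(self.image * 65535), 0, 65535).astype(np.uint16)
        else:
            raise ValueError("bit_depth must be 8 or 16")
        paths = {"image": str(outdir / "phantom.png"), "masks": [], "meta": str(outdir / "phantom.json")}
        iio.imwrite(paths["image"], img)
        for k, m in enumerate(self.masks):
            p = str(outdir / f"mask_{k}.png")
            iio.imwrite(p, (m.astype(np.uint8) * 255))
            paths["masks"].append(p)
        meta = {
            "gray_levels": list(map(float, self.gray_levels)),
            "sigma": float(self.sigma_target),
            "shape_style": self.shape_style,
            "seed": self.seed,
            "bit_depth": bit_depth,
        }
        with open(paths["meta"], "w") as fh:
            json.dump(meta, fh, indent=2)
        return paths


def _band_masks(width: int, height: int, n: int) -> list[np.ndarray]:
    edges = np.linspace(0, height, n + 1).round().astype(int)
    masks = []
    for k in range(n):
        m = np.zeros((height, width), dtype=bool)
        m[edges[k]:edges[k + 1], :] = True
        masks.append(m)
    return masks


def _disk_masks(width: int, height: int, n: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Region 0 is the background; regions 1..n-1 are non-overlapping disks."""
    yy, xx = np.mgrid[0:height, 0:width]
    placed: list[tuple[float, float, float]] = []
    masks = [np.ones((height, width), dtype=bool)]
    rmin = max(3, min(width, height) // 10)
    rmax = max(rmin + 1, min(width, height) // 5)
    for _ in range(n - 1):
        for _attempt in range(500):
            r = rng.integers(rmin, rmax + 1)
            cy = rng.integers(r + 1, height - r - 1)
            cx = rng.integers(r + 1, width - r - 1)
            # keep >= 2 px clearance so disk rims never touch each other
            if all((cy - py) ** 2 + (cx - px) ** 2 > (r + pr + 2) ** 2
                   for py, px, pr in placed):
                break
        else:
            raise ValueError(f"could not place {n - 1} non-overlapping disks on a "
                             f"{width}x{height} grid")
        placed.append((cy, cx, r))
        m = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
        masks.append(m)
        masks[0] &= ~m
    return masks


def _blob_masks(width: int, height: int, n: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Voronoi partition from n seeded random sites (irregular exact regions)."""
    for _attempt in range(100):
        sy = rng.uniform(0, height, size=n)
        sx = rng.uniform(0, width, size=n)
        yy, xx = np.mgrid[0:height, 0:width]
        d2 = (yy[..., None] - sy) ** 2 + (xx[..., None] - sx) ** 2
        lab = np.argmin(d2, axis=-1)
        if len(np.unique(lab)) == n:
            return [lab == k for k in range(n)]
    raise ValueError("could not draw a Voronoi partition with all regions nonempty")


def make_multilevel_phantom(width: int, height: int, n_regions: int,
                            gray_levels, shape_style: str = "bands",
                            seed: int = 0) -> Phantom:
    """Generate a multi-gray-level phantom with exact region masks.

    ``gray_levels`` must have one entry per region, each in [0, 1], pairwise
    distinct by at least 0.05.  ``shape_style`` is ``bands`` (horizontal
    stripes, equal heights when divisible), ``disks`` (region 0 background,
    the rest non-overlapping disks) or ``blobs`` (Voronoi cells).
    Deterministic for a fixed seed.
    """
    if not (1 <= n_regions <= 8):
        raise ValueError(f"n_regions must lie in [1, 8], got {n_regions}")
    levels = [float(g) for g in gray_levels]
    if len(levels) != n_regions:
        raise ValueError(f"expected {n_regions} gray levels, got {len(levels)}")
    if any(not (0.0 <= g <= 1.0) for g in levels):
        raise ValueError("gray levels must lie in [0, 1]")
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            if abs(levels[i] - levels[j]) < 0.05:
                raise ValueError(
                    f"gray levels {levels[i]} and {levels[j]} differ by less than 0.05; "
                    "regions would be statistically indistinguishable")
    rng = np.random.default_rng(seed)
    if shape_style == "bands":
        masks = _band_masks(width, height, n_regions)
    elif shape_style == "disks":
        masks = _disk_masks(width, height, n_regions, rng)
    elif shape_style == "blobs":
        masks = _blob_masks(width, height, n_regions, rng)
    else:
        raise ValueError(f"unknown shape_style {shape_style!r}")
    image = np.zeros((height, width), dtype=float)
    for g, m in zip(levels, masks):
        image[m] = g
    image = np.clip(image, 0.0, 1.0)
    return Phantom(image=image, masks=masks, gray_levels=levels,
                   sigma_target=float(np.std(image)), shape_style=shape_style,
                   seed=seed)


def add_gaussian_noise(image: np.ndarray, noise_sigma: float, seed: int = 0) -> np.ndarray:
    """Additive zero-mean Gaussian noise on the normalized scale, clipped to [0, 1]."""
    if noise_sigma < 0:
        raise ValueError(f"noise_sigma must be >= 0, got {noise_sigma}")
    arr = np.asarray(image, dtype=float)
    if noise_sigma == 0:
        return arr.copy()
    rng = np.random.default_rng(seed)
    return np.clip(arr + rng.normal(0.0, noise_sigma, size=arr.shape), 0.0, 1.0)


def two_band_phantom(width: int = 64, height: int = 64,
                     gray_levels=(0.2, 0.8), seed: int = 0) -> Phantom:
    """Equal-area two-band phantom; analytic σ = (g2 − g1)/2."""
    return make_multilevel_phantom(width, height, 2, gray_levels, "bands", seed)


def four_level_phantom(width: int = 96, height: int = 96,
                       shape_style: str = "bands", seed: int = 0,
                       gray_levels=FOUR_LEVEL_GRAY_LEVELS) -> Phantom:
    """The canonical four-level recovery phantom (geometric gray levels)."""
    return make_multilevel_phantom(width, height, 4, gray_levels, shape_style, seed)
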