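"""Synthetic inputs standing in for the experimental side of the study.

Three generators, all deterministic per seed:

* random osteonal microstructures -- random sequential placement of
  non-overlapping osteons (cement annuli included in the exclusion test)
  emulating a segmented embedded-cell window, with osteonal packing in the
  40-70% range typical of cortical bone;
* pseudo-experimental observables (peak force, tortuosity, J_Ic) obtained
  by running the forward model at known "true" tissue parameters and
  multiplying each observable by an independent median-preserving
  lognormal factor -- the ground truth for calibration-recovery tests;
* binary crack images with known analytic tortuosity, for validating the
  skeletonisation chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .geometry import Microstructure, Osteon

__all__ = [
    "MicrostructureRecipe",
    "PseudoExperiment",
    "generate_microstructure",
    "noisy_observables",
    "generate_pseudo_experiment",
    "generate_crack_image",
    "save_crack_mask",
]


def save_crack_mask(mask: np.ndarray, path) -> None:
    """Write a binary crack mask as an 8-bit PNG/TIFF image (0 / 255)."""
    import imageio.v3 as iio

    iio.imwrite(str(path), (np.asarray(mask, bool) * np.uint8(255)))


@dataclass(frozen=True)
class MicrostructureRecipe:
    """Packing parameters for a synthetic osteon layout.

    Radii in mm.  ``target_fraction`` is the osteonal area fraction
    (whole osteon discs, canal included, over the domain area); cortical
    bone sits around 0.4-0.7.  ``canal_ratio`` is r_canal / r_out.
    """

    target_fraction: float = 0.45
    r_out_mean: float = 0.075
    r_out_sd: float = 0.01
    canal_ratio: float = 1.0 / 3.0
    t_cem: float = 0.005
    min_gap: float = 0.002
    max_attempts_per_osteon: int = 10000
    seed: int = 0
    #: 'full' keeps whole osteons (annulus included) inside the region;
    #: 'canal' only keeps the canal well inside, letting lamellae straddle
    #: the window boundary the way traced embedded-cell windows do
    containment: str = "full"

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_fraction <= 0.75:
            raise ValueError("target_fraction must lie in [0, 0.75]")
        if self.r_out_mean <= 0.0 or self.r_out_sd < 0.0:
            raise ValueError("radius distribution must be positive")
        if not 0.0 < self.canal_ratio < 1.0:
            raise ValueError("canal_ratio must lie in (0, 1)")


def _domain_area(region: tuple) -> float:
    kind = region[0]
    if kind == "circle":
        return math.pi * region[3] ** 2
    if kind == "ellipse":
        return math.pi * region[3] * region[4]
    if kind == "rect":
        return (region[3] - region[1]) * (region[4] - region[2])
    raise ValueError(f"unknown region kind {kind!r}")


def _inside(region: tuple, x: float, y: float, margin: float) -> bool:
    kind = region[0]
    if kind == "circle":
        _, cx, cy, r = region
        return math.hypot(x - cx, y - cy) <= r - margin
    if kind == "ellipse":
        _, cx, cy, rx, ry = region
        return ((x - cx) / (rx - margin)) ** 2 + ((y - cy) / (ry - margin)) ** 2 <= 1.0
    if kind == "rect":
        _, x0, y0, x1, y1 = region
        return x0 + margin <= x <= x1 - margin and y0 + margin <= y <= y1 - margin
    raise ValueError(f"unknown region kind {kind!r}")


def generate_microstructure(
    recipe: MicrostructureRecipe, region: tuple
) -> Microstructure:
    """Random sequential adsorption of osteons into a region of interest.

    Osteons (with their cement annuli plus ``min_gap``) may not overlap and
    must lie fully inside the region.  Placement stops once the target
    osteonal area fraction is reached or the per-osteon attempt budget is
    exhausted; the achieved fraction is reported in the metadata-free
    return value via :meth:`Microstructure.osteonal_area_fraction`.

    ``region`` is ('circle', cx, cy, r), ('ellipse', cx, cy, rx, ry) or
    ('rect', x0, y0, x1, y1).  Deterministic per ``recipe.seed``.
    """
    rng = np.random.default_rng(recipe.seed)
    area = _domain_area(region)
    kind = region[0]
    if kind == "circle":
        lo = (region[1] - region[3], region[2] - region[3])
        hi = (region[1] + region[3], region[2] + region[3])
    elif kind == "ellipse":
        lo = (region[1] - region[3], region[2] - region[4])
        hi = (region[1] + region[3], region[2] + region[4])
    else:
        lo, hi = (region[1], region[2]), (region[3], region[4])

    osteons: list[Osteon] = []
    placed_area = 0.0
    target_area = recipe.target_fraction * area
    while placed_area < target_area:
        placed = False
        for _ in range(recipe.max_attempts_per_osteon):
            r_out = rng.normal(recipe.r_out_mean, recipe.r_out_sd)
            r_out = float(np.clip(r_out, 0.3 * recipe.r_out_mean, 2.0 * recipe.r_out_mean))
            x = rng.uniform(lo[0], hi[0])
            y = rng.uniform(lo[1], hi[1])
            if recipe.containment == "full":
                margin = r_out + recipe.t_cem
            else:
                margin = recipe.canal_ratio * r_out + 2.0 * recipe.t_cem
            if not _inside(region, x, y, margin):
                continue
            ok = True
            for o in osteons:
                lim = o.r_out + r_out + 2.0 * recipe.t_cem + recipe.min_gap
                if (o.x - x) ** 2 + (o.y - y) ** 2 < lim * lim:
                    ok = False
                    break
            if ok:
                osteons.append(
                    Osteon(x, y, r_out, recipe.canal_ratio * r_out)
                )
                placed_area += math.pi * r_out**2
                placed = True
                break
        if not placed:
            break  # jammed: return the partial packing
    micro = Microstructure(osteons=osteons, t_cem=recipe.t_cem, region=region)
    micro.validate()
    return micro


# ----------------------------------------------------------------------------
# pseudo-experiments
# ----------------------------------------------------------------------------


@dataclass(frozen=True)
class PseudoExperiment:
    """Noisy observables of a simulated specimen with known ground truth."""

    observed: dict  # name -> value (noise applied)
    truth: dict  # name -> noise-free forward value
    true_params: dict  # tissue parameter values used in the forward run
    noise_cv: float
    seed: int


def noisy_observables(base: dict, noise_cv: float, seed: int) -> dict:
    """Multiply each observable by an independent lognormal factor with
    median 1 and coefficient of variation ``noise_cv``."""
    if noise_cv < 0.0:
        raise ValueError("noise_cv must be non-negative")
    if noise_cv == 0.0:
        return dict(base)
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + noise_cv**2))
    return {
        k: float(v) * float(np.exp(rng.normal(0.0, sigma)))
        for k, v in sorted(base.items())
    }


def generate_pseudo_experiment(
    forward, true_params: dict, noise_cv: float, seed: int
) -> PseudoExperiment:
    """Run the forward model at known parameters and add observation noise.

    ``forward`` is a callable mapping a tissue-parameter dict to an
    observable dict (peak force N, tortuosity, J_Ic N/mm); the heavy
    simulation lives there so it can be cached by the caller.
    """
    base = forward(true_params)
    if any(v <= 0.0 for v in base.values()):
        raise ValueError(f"forward model returned non-positive observables: {base}")
    observed = noisy_observables(base, noise_cv, seed)
    return PseudoExperiment(
        observed=observed,
        truth=dict(base),
        true_params=dict(true_params),
        noise_cv=noise_cv,
        seed=seed,
    )


# ----------------------------------------------------------------------------
# synthetic crack images
# ----------------------------------------------------------------------------


def generate_crack_image(
    path_kind: str,
    shape: tuple = (200, 200),
    band_width: int = 5,
    amplitude: float | None = None,
) -> tuple[np.ndarray, float]:
    """Rasterise a crack band of known analytic tortuosity.

    ``path_kind``: 'straight' (vertical line, tortuosity 1), 'staircase45'
    (45-degree diagonal, sqrt(2)), 'sinusoid' (quarter sine of given
    amplitude, tortuosity from quadrature), 'arc' (quarter circle,
    pi/2 / 1).  Returns (binary image, analytic tortuosity); tortuosity is
    arc length over vertical extent.
    """
    ny, nx = shape
    ys = np.arange(ny, dtype=float)
    H = float(ny - 1)
    if path_kind == "straight":
        xs = np.full_like(ys, nx / 2.0)
        tort = 1.0
    elif path_kind == "staircase45":
        xs = ys * 1.0 + (nx - ny) / 2.0
        tort = math.sqrt(2.0)
    elif path_kind == "sinusoid":
        A = float(amplitude if amplitude is not None else nx / 4.0)
        xs = nx / 2.0 + A * np.sin(0.5 * math.pi * ys / H)
        arc, _ = quad(
            lambda t: math.hypot(1.0, A * 0.5 * math.pi / H * math.cos(0.5 * math.pi * t / H)),
            0.0,
            H,
        )
        tort = arc / H
    elif path_kind == "arc":
        R = H
        xs = nx * 0.1 + np.sqrt(np.maximum(R**2 - (H - ys) ** 2, 0.0))
        tort = (0.5 * math.pi * R) / H
    else:
        raise ValueError(f"unknown path kind {path_kind!r}")

    img = np.zeros((ny, nx), dtype=bool)
    cols = np.arange(nx, dtype=float)
    halfw = band_width / 2.0
    for iy in range(ny):
        img[iy] = np.abs(cols - xs[iy]) <= halfw
    return img, float(tort)
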