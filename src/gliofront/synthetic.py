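"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators:

* :func:`synth_confluency` — sparse-culture coverage time series grown from
  a prescribed per-cell rate curve r(A) with multiplicative log-normal
  noise, emulating time-lapse fields seeded at 3-100 cells/mm^2
  (initial coverages ~0.5-20%) and imaged every 10 minutes for ~4 days;
* :func:`synth_images` — textured-disk microscopy frames matching a target
  coverage sequence, with exact ground-truth masks (cells are rendered as
  high-local-variance disks on a smooth background; disk count, not disk
  growth, controls coverage, trading morphology for exact truth);
* :func:`synth_tail_profile` — the canonical post-resection state, an
  exponential density tail delta * exp(-a x) on a solver grid.

All generators are deterministic under a fixed seed and return their ground
truth next to the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from .growth import ConfluencySeries, ImageStack
from .solver import DensityProfile, Grid1D

__all__ = [
    "CultureSimSpec",
    "default_allee_rate",
    "synth_confluency",
    "synth_images",
    "synth_tail_profile",
]


def default_allee_rate(rho: float = 0.02, K: float = 0.9,
                       beta: float = 0.05) -> Callable:
    """Quadratic Allee per-cell rate in coverage units (1/h).

    Defaults are plausible for glioblastoma cultures: maximal rate scale
    0.02/h (doubling on the ~1.5 day scale), carrying coverage 0.9 and a
    weak Allee effect beta = 0.05.
    """
    def r(A):
        return rho * (np.asarray(A) / K + beta) * (1.0 - np.asarray(A) / K)

    r.params = {"rho": rho, "K": K, "beta": beta}
    return r


@dataclass
class CultureSimSpec:
    """Ground-truth settings for synthetic confluency series.

    ``A0`` seeds span initial coverages 0.5-20% (the sparse-culture regime);
    frames every 10 minutes for 96 h; 5% multiplicative log-normal noise.
    """

    r_curve: Callable = field(default_factory=default_allee_rate)
    A0: tuple = (0.005, 0.01, 0.02, 0.05, 0.1, 0.2)
    frame_interval_h: float = 1.0 / 6.0
    duration_h: float = 96.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        a0 = np.asarray(self.A0, dtype=float)
        if np.any((a0 <= 0) | (a0 >= 0.25)):
            raise ValueError("A0 values must lie in (0, 0.25) (sparse regime)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def synth_confluency(spec: CultureSimSpec, n_series: int | None = None
                     ) -> tuple[list[ConfluencySeries], dict]:
    """Integrate dA/dt = A r(A) per series and add multiplicative noise.

    ``n_series`` defaults to one series per A0 seed; more series cycle
    through the seeds. Returns (series list, ground truth) where the ground
    truth holds the noiseless trajectories and the rate curve used.
    """
    rng = np.random.default_rng(spec.seed)
    seeds = list(spec.A0)
    if n_series is None:
        n_series = len(seeds)
    t = np.arange(0.0, spec.duration_h + 1e-9, spec.frame_interval_h)
    series, truth_A = [], []
    capped = []
    for i in range(n_series):
        a0 = seeds[i % len(seeds)]
        sol = solve_ivp(lambda _, a: a * spec.r_curve(a), (t[0], t[-1]),
                        [a0], t_eval=t, rtol=1e-9, atol=1e-12,
                        method="RK45")
        A_true = sol.y[0]
        noise = np.exp(rng.normal(0.0, spec.noise_sd, size=A_true.shape)) \
            if spec.noise_sd > 0 else 1.0
        A = A_true * noise
        cap = A > 1.0
        if np.any(cap):
            A = np.minimum(A, 1.0)
        capped.append(bool(np.any(cap)))
        series.append(ConfluencySeries(f"s{i:02d}", t.copy(), A,
                                       seeding_density=None))
        truth_A.append(A_true)
    truth = {"times": t, "A_true": np.array(truth_A),
             "r_curve": spec.r_curve,
             "r_params": getattr(spec.r_curve, "params", None),
             "capped": capped, "seed": spec.seed}
    return series, truth


def _disk_offsets(radius_px: int) -> np.ndarray:
    """Pixel offsets (dy, dx) covered by a disk of the given radius."""
    r = int(radius_px)
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    inside = yy**2 + xx**2 <= r**2
    return np.stack([yy[inside], xx[inside]], axis=1)


def synth_images(series: ConfluencySeries, cell_radius_px: int = 30,
                 shape: tuple[int, int] = (1024, 1024),
                 texture_sd: float = 0.25, background_sd: float = 0.01,
                 seed: int = 0) -> tuple[ImageStack, np.ndarray]:
    """Render an image stack whose true coverage tracks ``series``.

    Cells are non-overlapping textured disks (zero-mean speckle of sd
    ``texture_sd`` added on a smooth background), so the segmentation
    oracle is the placed-disk mask. Disks persist between frames; count is
    adjusted per frame to match the target coverage within one disk's area.

    Returns (stack, true_masks). Raises if a target coverage is infeasible
    for non-overlapping packing (> 0.45).
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    offs = _disk_offsets(cell_radius_px)
    per_disk = len(offs) / (h * w)
    targets = np.asarray(series.A, dtype=float)
    if np.any(targets > 0.45):
        raise ValueError("target coverage > 0.45 infeasible for "
                         "non-overlapping disk packing")
    r = cell_radius_px
    centres: list[tuple[int, int]] = []

    def try_add() -> bool:
        for _ in range(2000):
            cy = rng.integers(r, h - r)
            cx = rng.integers(r, w - r)
            if all((cy - y) ** 2 + (cx - x) ** 2 > (2 * r + 1) ** 2
                   for (y, x) in centres):
                centres.append((int(cy), int(cx)))
                return True
        return False

    # smooth background: gentle plane + heavily blurred noise, shared by all
    # frames (stage drift etc. is not emulated)
    yy, xx = np.mgrid[0:h, 0:w]
    background = 0.5 + 0.05 * (xx / w - 0.5) + 0.03 * (yy / h - 0.5)
    from scipy.ndimage import gaussian_filter
    background = background + gaussian_filter(
        rng.normal(0.0, 1.0, shape), 25.0) * background_sd * 5

    frames = np.empty((len(targets), h, w))
    masks = np.zeros((len(targets), h, w), dtype=bool)
    for k, target in enumerate(targets):
        want = int(round(target / per_disk))
        while len(centres) < want:
            if not try_add():
                raise ValueError("disk packing failed; reduce coverage or "
                                 "radius")
        while len(centres) > want:
            centres.pop()
        mask = np.zeros(shape, dtype=bool)
        for (cy, cx) in centres:
            mask[offs[:, 0] + cy, offs[:, 1] + cx] = True
        frame = background + rng.normal(0.0, background_sd, shape)
        speckle = rng.normal(0.0, texture_sd, shape)
        frame[mask] += speckle[mask]
        frames[k] = frame
        masks[k] = mask
    stack = ImageStack(frames, series.times[:len(targets)].copy(),
                       field_id=series.series_id)
    return stack, masks


def synth_tail_profile(delta: float, a: float, grid: Grid1D
                       ) -> DensityProfile:
    """Exponential post-resection tail delta*exp(-a x) for x >= 0 on a grid.

    The grid must extend to at least 10/a so that the tail (and its mass
    delta/a) is essentially fully contained.
    """
    if a <= 0:
        raise ValueError("a must be > 0")
    if delta <= 0:
        raise ValueError("delta must be > 0")
    x = grid.x
    if x[-1] < 10.0 / a:
        raise ValueError("grid too short: needs to reach x = 10/a")
    C = np.where(x >= 0, delta * np.exp(-a * np.maximum(x, 0.0)), 0.0)
    return DensityProfile(grid, C, 0.0)
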