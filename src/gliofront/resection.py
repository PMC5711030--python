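"""Surgical resection operator on a density profile.

Resection is modelled as resetting the cancer-cell density to zero wherever
it exceeds a detection threshold delta, leaving behind only the
sub-threshold infiltrative tail(s). Two variants are supported:

* ``excise_no_flux`` — the super-threshold region is removed from the
  computational domain: its nodes are deactivated and a no-flux condition
  holds at the excision contour, so the cavity cannot be repopulated;
* ``zero_fill`` — the density is set to zero but the nodes stay active, so
  back-propagation into the cavity remains possible.

Recurrence delays are insensitive to this choice for Allee-type growth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .solver import DensityProfile, total_mass

__all__ = ["ResectionSpec", "ResectionOutcome", "NothingToResect", "resect"]

_MODES = ("excise_no_flux", "zero_fill")


class NothingToResect(ValueError):
    """The profile never exceeds the detection threshold."""


@dataclass(frozen=True)
class ResectionSpec:
    """Detection threshold, intervention time and cavity handling mode."""

    delta: float
    t_s: float = 0.0
    mode: str = "excise_no_flux"

    def __post_init__(self) -> None:
        if not (self.delta > 0):
            raise ValueError(f"delta must be > 0, got {self.delta}")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")


@dataclass
class ResectionOutcome:
    """Post-resection profile plus book-keeping of what was removed."""

    profile: DensityProfile
    resected_intervals: list[tuple[float, float]]
    removed_mass: float

    @property
    def resected_interval(self) -> tuple[float, float]:
        """Convex hull of all removed intervals."""
        return (self.resected_intervals[0][0], self.resected_intervals[-1][1])


def _crossing(x: np.ndarray, C: np.ndarray, i: int, j: int, delta: float) -> float:
    """Linearly interpolated position of the delta-crossing between nodes."""
    if C[j] == C[i]:
        return float(x[i])
    frac = (delta - C[i]) / (C[j] - C[i])
    return float(x[i] + frac * (x[j] - x[i]))


def resect(profile: DensityProfile, spec: ResectionSpec) -> ResectionOutcome:
    """Remove all density above the detection threshold.

    Every node with C > delta is zeroed; in ``excise_no_flux`` mode those
    nodes are also deactivated. Interval edges are reported at the linearly
    interpolated delta-crossings (sub-grid localisation matters because the
    recurrence delay scales as delta^-2). Multiple disjoint super-threshold
    regions are all resected, with a warning.

    Raises
    ------
    NothingToResect
        If the profile maximum is at or below delta.
    """
    C, x, act = profile.C, profile.grid.x, profile.active
    above = act & (C > spec.delta)
    if not above.any():
        raise NothingToResect(
            f"maximum density {C[act].max() if act.any() else 0.0:.4g} "
            f"does not exceed delta = {spec.delta}")

    idx = np.flatnonzero(above)
    splits = np.flatnonzero(np.diff(idx) > 1)
    blocks = np.split(idx, splits + 1)
    if len(blocks) > 1:
        warnings.warn(f"{len(blocks)} disjoint super-threshold regions; "
                      "resecting all of them", stacklevel=2)

    pre_mass = total_mass(profile)
    new_C = C.copy()
    new_act = act.copy()
    intervals: list[tuple[float, float]] = []
    for block in blocks:
        i0, i1 = int(block[0]), int(block[-1])
        # interpolated contour positions (clipped to the active extent)
        if i0 > 0 and act[i0 - 1]:
            x_lo = _crossing(x, C, i0 - 1, i0, spec.delta)
        else:
            x_lo = x[i0] - profile.grid.dx / 2
        if i1 < len(C) - 1 and act[i1 + 1]:
            x_hi = _crossing(x, C, i1 + 1, i1, spec.delta)
        else:
            x_hi = x[i1] + profile.grid.dx / 2
        intervals.append((x_lo, x_hi))
        new_C[i0:i1 + 1] = 0.0
        if spec.mode == "excise_no_flux":
            new_act[i0:i1 + 1] = False

    post = DensityProfile(profile.grid, new_C, profile.t, new_act)
    removed = pre_mass - total_mass(post)
    return ResectionOutcome(profile=post, resected_intervals=intervals,
                            removed_mass=removed)


def auto_resection_time(params, travel_widths: float = 10.0) -> float:
    """Default intervention time: when the front has travelled
    ``travel_widths`` front widths at the asymptotic pulled-front speed
    2 sqrt(D rho) (used as a scale even for Allee runs, whose pushed fronts
    are slower — the resulting t_s is then conservative)."""
    speed = 2.0 * np.sqrt(params.D * params.rho)
    return travel_widths * params.front_width / speed
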