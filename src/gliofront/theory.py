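"""Closed-form estimates of the post-resection remission time.

After resection at threshold delta, the tumour is reduced to the
exponential leading-edge tail

    C(x, 0) = delta * exp(-a x),   x > 0,   a = sqrt(rho / D).

For delta/K << 1 diffusion initially dominates proliferation (borderline
Allee case beta = 0, where the low-density reaction is the quadratic
rho C^2 / K), so the early evolution is approximately pure diffusion of the
tail. The diffusion solution spreads the tail into a mass-conserving
Gaussian of total mass delta/a; recurrence begins once the quadratic
proliferation term catches up with the decaying diffusion term at the
density maximum x = 0, which yields a remission time scaling as

    tau ~ (K / delta)^2 / rho,

i.e. inversely proportional to the square of the detection threshold.

Two variants of the proportionality constant are provided because the
source balance argument admits both readings:

* ``eq11_as_printed``: tau = (1 / (pi rho)) (K / delta)^2,
* ``eq10_rebalanced``: tau = (pi / rho) (K / delta)^2, obtained by solving
  the term balance  C/(2 tau) = rho C^2 / K  at x = 0 with
  C(0, tau) = delta / (2 sqrt(pi rho tau)).

They share the delta^-2 law and differ by the constant factor pi^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special

from .models import ModelParams

__all__ = [
    "TailSpec",
    "TermBalance",
    "initial_term_balance",
    "diffusion_solution",
    "gaussian_approx",
    "late_term_balance",
    "remission_time_theory",
]


@dataclass(frozen=True)
class TailSpec:
    """Post-resection exponential tail delta * exp(-a x)."""

    delta: float
    params: ModelParams
    a: float | None = None

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if self.a is None:
            object.__setattr__(self, "a", self.params.tail_rate)
        elif self.a <= 0:
            raise ValueError("a must be > 0")

    @property
    def tail_mass(self) -> float:
        """Integral of the tail over x > 0: delta / a."""
        return self.delta / self.a


@dataclass(frozen=True)
class TermBalance:
    """Diffusion and proliferation contributions to dC/dt at one (x, t)."""

    diffusion: float | np.ndarray
    proliferation: float | np.ndarray

    @property
    def ratio(self):
        """|diffusion| / proliferation (np.inf where proliferation = 0)."""
        with np.errstate(divide="ignore"):
            return np.abs(self.diffusion) / np.abs(self.proliferation)


def initial_term_balance(x, spec: TailSpec) -> TermBalance:
    """Term magnitudes right after resection, from the tail profile.

    With C = delta e^{-a x} and a^2 D = rho, the diffusion term is
    rho delta e^{-a x} and the quadratic (beta = 0) proliferation term is
    rho delta^2 / K e^{-2 a x}; their ratio (K/delta) e^{a x} >> 1 for a
    small detection threshold, so diffusion dominates initially.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be >= 0 (tail support)")
    p, a, d = spec.params, spec.a, spec.delta
    diff = p.rho * d * np.exp(-a * x)
    prol = p.rho * d**2 / p.K * np.exp(-2.0 * a * x)
    if x.ndim == 0:
        return TermBalance(float(diff), float(prol))
    return TermBalance(diff, prol)


def diffusion_solution(x, t, spec: TailSpec):
    """Early-time pure-diffusion evolution of the truncated tail.

    Evaluates, verbatim,

        C(x,t) = (delta/2) [1 - erf((rho t - x) / (2 sqrt(D t)))]
                 * exp(-a x + rho t).

    Overflow in the exp factor is avoided by the scaled complementary error
    function (erfcx), combining both exponents analytically. Note this
    expression is the short-time approximation only; its long-time
    behaviour is superseded by :func:`gaussian_approx`.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("t must be > 0")
    p, a, d = spec.params, spec.a, spec.delta
    z = (p.rho * t - x) / (2.0 * np.sqrt(p.D * t))
    # (1 - erf(z)) e^{E} = erfcx(z) e^{E - z^2} for z >= 0
    expo = -a * x + p.rho * t
    pos = z >= 0
    out = np.where(
        pos,
        special.erfcx(np.maximum(z, 0.0)) * np.exp(expo - z**2),
        special.erfc(np.minimum(z, 0.0)) * np.exp(np.where(pos, -np.inf, expo)),
    ) * (d / 2.0)
    return float(out) if out.ndim == 0 else out


def gaussian_approx(x, t, spec: TailSpec):
    """Long-time Gaussian form of the dispersed tail,

        C(x, t) = delta / (2 sqrt(pi rho t)) * exp(-x^2 / (4 D t)),

    a heat-kernel profile of constant total mass delta sqrt(D/rho)
    = delta / a (integrated over the whole line).
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("t must be > 0")
    p, d = spec.params, spec.delta
    out = d / (2.0 * np.sqrt(np.pi * p.rho * t)) * np.exp(
        -x**2 / (4.0 * p.D * t))
    return float(out) if out.ndim == 0 else out


def late_term_balance(x, t, spec: TailSpec) -> TermBalance:
    """Term magnitudes in the late, Gaussian regime.

    Substituting the Gaussian form C(x,t) back into the PDE gives

        diffusion     = D C(x,t) (x^2/(4 D^2 t^2) - 1/(2 D t)),
        proliferation = rho C(x,t)^2 / K        (quadratic, beta = 0).

    At the density maximum x = 0 the diffusion term is -C/(2t); the
    remission-time balance equates its magnitude with the proliferation
    term there.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("t must be > 0")
    p = spec.params
    C = gaussian_approx(x, t, spec)
    diff = p.D * C * (x**2 / (4.0 * p.D**2 * t**2) - 1.0 / (2.0 * p.D * t))
    prol = p.rho * np.asarray(C) ** 2 / p.K
    if np.ndim(diff) == 0:
        return TermBalance(float(diff), float(prol))
    return TermBalance(diff, prol)


def remission_time_theory(delta: float, params: ModelParams,
                          variant: str = "eq11_as_printed") -> float:
    """Closed-form remission time for the borderline (beta = 0) Allee case.

    Both variants scale exactly as delta^-2 and differ only in the
    prefactor (see module docstring):

    * ``eq11_as_printed``:  (1 / (pi rho)) (K / delta)^2
    * ``eq10_rebalanced``:  (pi / rho) (K / delta)^2
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    if delta >= params.K:
        warnings.warn("delta >= K: the small-threshold asymptotics do not "
                      "apply", stacklevel=2)
    ratio2 = (params.K / delta) ** 2
    if variant == "eq11_as_printed":
        return ratio2 / (np.pi * params.rho)
    if variant == "eq10_rebalanced":
        return np.pi * ratio2 / params.rho
    raise ValueError(f"unknown variant {variant!r}")
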