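"""Proliferation laws for invasive tumour growth.

Two net per-cell proliferation rates r(C) are supported, both vanishing at
the carrying capacity K:

* logistic:  r(C) = rho * (1 - C/K), monotonically decreasing in C;
* allee:     r(C) = rho * (C/K + beta) * (1 - C/K), a quadratic law whose
  low-density branch *increases* with density (cooperative growth).

The Allee law is classified by the sign of beta: beta < 0 is a *strong*
Allee effect with a critical density C_T = -beta*K below which the net rate
is negative (bistable population dynamics); beta > 0 is a *weak* Allee
effect (rate always positive below K); beta = 0 is the borderline case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelParams",
    "per_cell_rate",
    "net_growth",
    "classify_allee",
    "critical_density",
    "asymptotic_speed",
]

_KINDS = ("logistic", "allee")


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the reaction-diffusion model.

    Attributes
    ----------
    D : float
        Cell diffusivity (length^2 / time), > 0.
    rho : float
        Maximum net per-cell proliferation rate (1 / time), > 0.
    K : float
        Carrying capacity (cells / length), > 0.
    beta : float
        Dimensionless Allee parameter; ignored for ``kind="logistic"``.
    kind : {"logistic", "allee"}
        Which proliferation law to use.
    """

    D: float = 1.0
    rho: float = 1.0
    K: float = 1.0
    beta: float = 0.0
    kind: str = "logistic"

    def __post_init__(self) -> None:
        for name in ("D", "rho", "K"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        if not np.isfinite(self.beta):
            raise ValueError(f"beta must be finite, got {self.beta!r}")
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.kind == "allee" and self.beta <= -1:
            warnings.warn(
                "beta <= -1 makes r(C) <= 0 on all of (0, K); the population "
                "cannot invade anywhere",
                stacklevel=2,
            )

    # Characteristic scales of the travelling front -----------------------
    @property
    def front_width(self) -> float:
        """Characteristic width sqrt(D/rho) of the invasion front."""
        return float(np.sqrt(self.D / self.rho))

    @property
    def tail_rate(self) -> float:
        """Leading-edge exponential decay rate a = sqrt(rho/D)."""
        return float(np.sqrt(self.rho / self.D))

    @property
    def fisher_speed(self) -> float:
        """Linear (pulled-front) spreading speed 2*sqrt(D*rho*r(0)/rho).

        For the logistic law this is the classic 2*sqrt(D*rho); for an
        Allee law with beta > 0 the linearisation at C=0 gives
        2*sqrt(D*rho*beta), and 0 for beta <= 0.
        """
        if self.kind == "logistic":
            return 2.0 * float(np.sqrt(self.D * self.rho))
        return 2.0 * float(np.sqrt(self.D * self.rho * max(self.beta, 0.0)))


def _check_density(C: np.ndarray) -> np.ndarray:
    C = np.asarray(C, dtype=float)
    if not np.all(np.isfinite(C)):
        raise ValueError("density contains non-finite values")
    if np.any(C < 0):
        raise ValueError("density must be non-negative")
    return C


def per_cell_rate(C, params: ModelParams):
    """Net per-cell proliferation rate r(C) (1/time).

    Exact evaluation with no clipping: densities above K simply yield a
    negative rate, and for a strong Allee effect the rate is negative for
    0 < C < -beta*K.
    """
    C = _check_density(C)
    u = C / params.K
    if params.kind == "logistic":
        r = params.rho * (1.0 - u)
    else:
        r = params.rho * (u + params.beta) * (1.0 - u)
    return r if r.ndim else float(r)


def net_growth(C, params: ModelParams):
    """Density growth rate C * r(C) — the reaction term of the PDE."""
    C = _check_density(C)
    f = C * per_cell_rate(C, params)
    return f if np.ndim(f) else float(f)


def classify_allee(params: ModelParams) -> str:
    """Classify the proliferation law.

    Returns ``"logistic"``, ``"strong"`` (beta < 0), ``"weak"`` (beta > 0)
    or ``"borderline"`` (beta = 0).
    """
    if params.kind == "logistic":
        return "logistic"
    if params.beta < 0:
        return "strong"
    if params.beta > 0:
        return "weak"
    return "borderline"


def critical_density(params: ModelParams):
    """Critical survival density C_T = -beta*K for a strong Allee effect.

    Below C_T the net growth rate is negative and a uniform population goes
    extinct. Returns ``None`` for logistic or weak/borderline Allee laws,
    which have no critical survival density.
    """
    if classify_allee(params) == "strong":
        return -params.beta * params.K
    return None


def asymptotic_speed(params: ModelParams) -> float:
    """Asymptotic travelling-front speed of the invasion model.

    Logistic growth gives the classic pulled-front speed 2 sqrt(D rho).
    For the quadratic Allee law the front is *pushed* for beta < 1/2 with
    the exact speed sqrt(D rho / 2) (1 + 2 beta) (negative for
    beta < -1/2: a retreating bistable front), and pulled with speed
    2 sqrt(D rho beta) for beta >= 1/2.
    """
    s = float(np.sqrt(params.D * params.rho))
    if params.kind == "logistic":
        return 2.0 * s
    if params.beta >= 0.5:
        return 2.0 * s * float(np.sqrt(params.beta))
    return s * (1.0 + 2.0 * params.beta) / float(np.sqrt(2.0))
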