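"""Inhibitory-field strength functions for the four models.

Each existing primordium emits an inhibitory power whose effect decreases
with distance; a new primordium can only arise where the summed field is
weakest (DC1/EDC1) or drops below a threshold (DC2/EDC2).  The expanded
models (EDC1, EDC2) multiply each primordium's contribution by a logistic
function of its age, so the inhibitory power may rise or fall as a
primordium matures -- the ingredient that makes orixate phyllotaxis
(divergence cycle 180, 90, -180, -90 degrees) attainable.

Kernels
-------
DC1/EDC1 : power law ``k d^-eta`` on the planar distance.
DC2/EDC2 : threshold-shaped ``E(x) = Es (coth(a x) - 1)/(coth(a) - 1)`` on
    the conical distance scaled by the inhibition range ``d0``; ``E(1) = Es``
    exactly, so ``d0`` is the distance at which a lone primordium just stops
    excluding a newcomer.  Evaluated in the equivalent stable form
    ``Es * expm1(2 alpha) / expm1(2 alpha x)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import conical_distance, planar_distance

__all__ = [
    "DC1Params",
    "EDC1Params",
    "DC2Params",
    "EDC2Params",
    "GammaRamp",
    "age_factor_edc1",
    "age_factor_edc2",
    "decay_dc1",
    "decay_dc2",
    "field_dc1",
    "field_dc2",
    "field_dc2_at",
]

# exponent cap for expm1: e^700 is finite in float64, the quotient underflows
# to ~1e-300 long before distances get this far
_EXP_CAP = 700.0


@dataclass(frozen=True, kw_only=True)
class DC1Params:
    """Plain DC1: planar apex, one primordium per plastochron.

    eta : distance-decay exponent of the power-law kernel.
    G   : growth per plastochron, ``G = V0 T / R0 = ln(r_m / r_{m+1})``.
    k   : proportionality coefficient (scales the field, never the argmin).
    """

    eta: float
    G: float
    k: float = 1.0

    def __post_init__(self):
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.G <= 0:
            raise ValueError("G must be positive")
        if self.k <= 0:
            raise ValueError("k must be positive")

    @property
    def age_params(self):
        return None


@dataclass(frozen=True, kw_only=True)
class EDC1Params(DC1Params):
    """EDC1: DC1 plus a logistic age dependence of the inhibitory power.

    ``F(age) = 1 / (1 + exp(-a (age - b)))`` with age in plastochron units;
    ``a`` is the rate and ``b`` the timing of the change.  ``eta`` defaults
    to 2, the value used for all EDC1 analyses here.
    """

    eta: float = 2.0
    a: float = 0.0
    b: float = 0.0

    @property
    def age_params(self):
        return (self.a, self.b)


@dataclass(frozen=True, kw_only=True)
class DC2Params:
    """Plain DC2: conical apex, threshold-triggered primordium insertion.

    alpha : steepness of the kernel's decline around the threshold distance.
    Gamma : inhibition range over SAM size, ``Gamma = d0 / (R0 N)``.
    N     : apex flatness ``sin(psi/2)`` in (0, 1].
    Es    : threshold field strength (1 throughout this work).
    distance_variant : reading of the smoothed conical distance
        (see :func:`phyllosim.geometry.conical_distance`).
    """

    alpha: float
    Gamma: float
    N: float = 1.0 / 3.0
    Es: float = 1.0
    distance_variant: str = "chord"

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.Gamma <= 0:
            raise ValueError("Gamma must be positive")
        if not (0.0 < self.N <= 1.0):
            raise ValueError("N must lie in (0, 1]")
        if self.distance_variant not in ("chord", "scaled"):
            raise ValueError(f"unknown distance_variant {self.distance_variant!r}")

    @property
    def d0(self) -> float:
        """Maximum exclusion distance, ``Gamma * R0 * N`` (R0 = 1)."""
        return self.Gamma * self.N

    @property
    def age_params(self):
        return None

    def gamma_at(self, t_sim: float) -> float:
        return self.Gamma


@dataclass(frozen=True)
class GammaRamp:
    """Smooth tanh schedule for Gamma(t_sim), used to ease pattern onset.

    ``Gamma(t) = (Gi + Gf)/2 - (Gi - Gf)/2 * tanh((t - ti)/tau)``.
    """

    Gamma_i: float = 50.0
    Gamma_f: float = 2.8
    t_i: float = 0.2
    tau: float = 0.3

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.Gamma_i <= 0 or self.Gamma_f <= 0:
            raise ValueError("Gamma values must be positive")

    def __call__(self, t_sim: float) -> float:
        return 0.5 * (self.Gamma_i + self.Gamma_f) - 0.5 * (
            self.Gamma_i - self.Gamma_f
        ) * np.tanh((t_sim - self.t_i) / self.tau)


@dataclass(frozen=True, kw_only=True)
class EDC2Params(DC2Params):
    """EDC2: DC2 plus a logistic age dependence of the inhibitory power.

    ``F(t) = 1 / (1 + exp(-A (t - B)))`` with the primordium age ``t`` in
    standardized time; ``A`` is the rate and ``B`` the timing.  An optional
    ``ramp`` makes Gamma itself a function of simulation time.
    """

    A: float = 0.0
    B: float = 0.0
    ramp: GammaRamp | None = None

    @property
    def age_params(self):
        return (self.A, self.B)

    def gamma_at(self, t_sim: float) -> float:
        return self.ramp(t_sim) if self.ramp is not None else self.Gamma


def age_factor_edc1(age, a: float, b: float):
    """Logistic inhibitory-power factor for EDC1 (age in plastochrons).

    Increasing in age for ``a > 0``, decreasing for ``a < 0``; exactly 0.5
    at ``age = b`` or everywhere when ``a = 0``.
    """
    x = -a * (np.asarray(age, dtype=float) - b)
    out = 1.0 / (1.0 + np.exp(np.minimum(x, _EXP_CAP)))
    return float(out) if out.ndim == 0 else out


def age_factor_edc2(age, A: float, B: float):
    """Logistic inhibitory-power factor for EDC2 (age in standardized time)."""
    return age_factor_edc1(age, A, B)


def decay_dc1(d, eta: float, k: float = 1.0):
    """Power-law inhibition ``k d^-eta`` of one primordium at distance d."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("distance must be positive (coincident points?)")
    out = k * d ** (-eta)
    return float(out) if out.ndim == 0 else out


def decay_dc2(x, alpha: float, Es: float = 1.0):
    """Threshold-shaped inhibition of one primordium at scaled distance x.

    ``E(x) = Es (coth(alpha x) - 1)/(coth(alpha) - 1)``, monotonically
    decreasing and downward-convex with ``E(1) = Es``, divergent at 0 and
    vanishing at infinity.  Computed as
    ``Es * expm1(2 alpha) / expm1(2 alpha x)``, which is exact algebraically
    and stable where ``1/tanh`` would lose precision.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("scaled distance x must be positive")
    num = Es * np.expm1(2.0 * alpha)
    out = num / np.expm1(np.minimum(2.0 * alpha * x, _EXP_CAP))
    return float(out) if out.ndim == 0 else out


def _as_arrays(primordia):
    thetas = np.array([p.theta for p in primordia], dtype=float)
    births = np.array([p.birth_time for p in primordia], dtype=float)
    return thetas, births


def field_dc1(theta_grid, primordia, params: DC1Params, n: int | None = None):
    """DC1/EDC1 inhibitory field on the circle *M* at each grid angle.

    The field when the ``n``-th primordium is arising: each preceding
    primordium ``m`` sits at radius ``exp(G (n - m))`` (in units of R0) and
    contributes ``k d^-eta`` times, for EDC1, its logistic age factor
    ``F(n - m)``.

    Parameters
    ----------
    theta_grid : array of degrees covering [0, 360).
    primordia : ordered sequence of preceding primordia (indices 1..n-1).
    n : index of the incipient primordium; defaults to ``len(primordia)+1``.
    """
    if len(primordia) == 0:
        raise ValueError("at least one preceding primordium is required")
    if n is None:
        n = len(primordia) + 1
    thetas, _ = _as_arrays(primordia)
    ages = n - np.array([p.index for p in primordia], dtype=float)
    if np.any(ages <= 0):
        raise ValueError("all primordia must precede the incipient one")
    r = np.exp(params.G * ages)
    grid = np.asarray(theta_grid, dtype=float)
    d = planar_distance(
        (1.0, grid[:, None]), (r[None, :], thetas[None, :])
    )
    contrib = decay_dc1(d, params.eta, params.k)
    ap = params.age_params
    if ap is not None:
        contrib = contrib * age_factor_edc1(ages, *ap)[None, :]
    return contrib.sum(axis=1)


def field_dc2_at(points, primordia, now: float, params: DC2Params):
    """DC2/EDC2 inhibitory field at arbitrary ``(r, theta)`` query points.

    Each existing primordium sits at radius ``exp(now - birth_time)`` and
    contributes ``E(d/d0)`` (times its EDC2 age factor) through the modified
    conical distance ``d``.  A query point coinciding with a primordium gets
    an infinite field value.
    """
    r_q, t_q = points
    thetas, births = _as_arrays(primordia)
    if np.any(births > now + 1e-15):
        raise ValueError("primordium born after 'now'")
    ages = np.maximum(now - births, 0.0)
    r = np.exp(ages)
    gamma = params.gamma_at(now)
    d0 = gamma * params.N
    r_q = np.asarray(r_q, dtype=float)
    t_q = np.asarray(t_q, dtype=float)
    d = conical_distance(
        (r_q[..., None], t_q[..., None]),
        (r[None, :], thetas[None, :]),
        params.N,
        variant=params.distance_variant,
    )
    x = d / d0
    num = params.Es * np.expm1(2.0 * params.alpha)
    with np.errstate(divide="ignore"):
        contrib = num / np.expm1(np.minimum(2.0 * params.alpha * x, _EXP_CAP))
    contrib = np.where(x == 0.0, np.inf, contrib)
    ap = params.age_params
    if ap is not None:
        contrib = contrib * age_factor_edc2(ages, *ap)[None, :]
    return contrib.sum(axis=-1)


def field_dc2(theta_grid, primordia, now: float, params: DC2Params):
    """DC2/EDC2 inhibitory field on the circle *M* (query radius ``R0``)."""
    grid = np.asarray(theta_grid, dtype=float)
    return field_dc2_at((np.ones_like(grid), grid), primordia, now, params)
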