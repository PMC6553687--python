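"""Apex geometry shared by all inhibitory-field phyllotaxis models.

The shoot apex is idealized either as a plane (DC1-family models) or as a
cone with apical angle psi (DC2-family models).  New primordia arise on the
circle *M* of radius ``R0`` around the apex center and then recede radially
because the apex grows exponentially.  All lengths are expressed in units of
``R0`` and all times are standardized (multiplied by ``V0/R0``), so the
default apex has ``R0 = V0 = 1``.

Angles are degrees in ``[0, 360)`` at every public interface; divergence
angles elsewhere in the package are reported signed in ``(-180, 180]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Primordium",
    "ApexModel",
    "wrap_360",
    "wrap_180",
    "radial_distance",
    "planar_distance",
    "conical_distance",
]


def wrap_360(theta):
    """Wrap an angle (degrees) into ``[0, 360)``."""
    return np.asarray(theta) % 360.0 if np.ndim(theta) else float(theta) % 360.0


def wrap_180(delta):
    """Wrap an angular difference (degrees) into ``(-180, 180]``.

    The boundary maps to +180 so that opposite placement is reported as a
    +180 degree divergence, matching the sign convention used throughout.
    """
    d = np.asarray(delta, dtype=float)
    w = d % 360.0
    w = np.where(w > 180.0, w - 360.0, w)
    w = np.where(w == -180.0, 180.0, w)
    return float(w) if np.ndim(delta) == 0 else w


@dataclass(frozen=True)
class Primordium:
    """One lateral-organ initiation event.

    Parameters
    ----------
    index : int
        1-based birth order.
    theta : float
        Azimuth on the apex, degrees in ``[0, 360)``.
    birth_time : float
        Standardized birth time (units of ``R0/V0``).  For DC1-family runs
        this is the iteration index times one plastochron.
    """

    index: int
    theta: float
    birth_time: float

    def __post_init__(self):
        if self.index < 1:
            raise ValueError(f"index must be a positive integer, got {self.index}")
        object.__setattr__(self, "theta", wrap_360(self.theta))

    def radius(self, now: float, apex: "ApexModel | None" = None) -> float:
        """Radial distance from the apex center at standardized time ``now``."""
        return radial_distance(self.birth_time, now, apex or ApexModel())


@dataclass(frozen=True)
class ApexModel:
    """Geometry of the shoot apex.

    ``N = sin(psi/2)`` is the dimensionless flatness of the cone; ``N = 1``
    recovers the plane.  ``R0`` is the radius of the primordium-formation
    circle *M* and ``V0`` the initial radial velocity; both default to 1 by
    normalization.
    """

    R0: float = 1.0
    N: float = 1.0
    V0: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.N <= 1.0):
            raise ValueError(f"flatness N must lie in (0, 1], got {self.N}")
        if self.R0 <= 0:
            raise ValueError(f"R0 must be positive, got {self.R0}")
        if self.V0 <= 0:
            raise ValueError(f"V0 must be positive, got {self.V0}")


def radial_distance(birth_time, now, apex: ApexModel | None = None):
    """Radial position ``R0 * exp(now - birth_time)`` of a primordium.

    Exponential apex growth carries every primordium radially outward; its
    distance from the center depends only on its standardized age.

    Raises
    ------
    ValueError
        If any age ``now - birth_time`` is negative (a sequencing bug).
    """
    apex = apex or ApexModel()
    age = np.asarray(now, dtype=float) - np.asarray(birth_time, dtype=float)
    if np.any(age < 0):
        raise ValueError("negative primordium age: 'now' precedes birth_time")
    r = apex.R0 * np.exp(age)
    return float(r) if r.ndim == 0 else r


def planar_distance(p_query, p_prim):
    """Euclidean distance in the apex plane between ``(r, theta)`` points.

    Law of cosines: ``sqrt(r1^2 + r2^2 - 2 r1 r2 cos(dtheta))`` with angles
    in degrees.  Used by DC1/EDC1.
    """
    r1, t1 = p_query
    r2, t2 = p_prim
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if np.any(r1 < 0) or np.any(r2 < 0):
        raise ValueError("radii must be non-negative")
    dphi = np.radians(np.asarray(t1, dtype=float) - np.asarray(t2, dtype=float))
    d2 = r1 * r1 + r2 * r2 - 2.0 * r1 * r2 * np.cos(dphi)
    d = np.sqrt(np.maximum(d2, 0.0))
    return float(d) if d.ndim == 0 else d


def conical_distance(p1, p2, N: float, variant: str = "chord"):
    """Smoothed distance between two points on the conical apex surface.

    The default ``variant='chord'`` is the three-dimensional Euclidean
    chord between points at slope distances ``r`` on a cone of flatness
    ``N = sin(psi/2)``:

        ``sqrt((r1 - r2)^2 + 2 N^2 r1 r2 (1 - cos(dtheta)))``

    It coincides with the unrolled-cone (geodesic) distance to second order
    in the azimuthal separation while staying smooth and monotone over the
    full circle, which is exactly the discontinuity fix the DC2 model needs:
    the naive unrolled distance is non-smooth for widely separated points.
    For ``N = 1`` it reduces to the planar law-of-cosines distance for all
    radii.

    ``variant='scaled'`` applies the flatness as an overall multiplier,
    ``sqrt(N) * planar_distance`` -- kept switchable because the published
    formula is typographically ambiguous; only the chord variant reproduces
    the documented DC2 pattern sequence (distichous at large inhibition
    range shifting to spirals as it shrinks).
    """
    if not (0.0 < N <= 1.0):
        raise ValueError(f"flatness N must lie in (0, 1], got {N}")
    r1, t1 = p1
    r2, t2 = p2
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if np.any(r1 < 0) or np.any(r2 < 0):
        raise ValueError("radii must be non-negative")
    dphi = np.radians(np.asarray(t1, dtype=float) - np.asarray(t2, dtype=float))
    dr = r1 - r2
    if variant == "chord":
        d2 = dr * dr + 2.0 * N * N * r1 * r2 * (1.0 - np.cos(dphi))
    elif variant == "scaled":
        d2 = N * (dr * dr + 2.0 * r1 * r2 * (1.0 - np.cos(dphi)))
    else:
        raise ValueError(f"unknown conical-distance variant {variant!r}")
    d = np.sqrt(np.maximum(d2, 0.0))
    return float(d) if d.ndim == 0 else d
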