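"""Fixed-arrangement analyses of normal orixate phyllotaxis.

Normal orixate phyllotaxis places successive primordia with the divergence
cycle 180, 90, -180, -90 degrees, so all primordia lie on two orthogonal
axes and every fourth one shares an axis direction.  This module builds
such idealized arrangements, evaluates the inhibitory-field landscape they
generate on the formation circle *M*, and asks when the incipient
primordium position (0 degrees by convention) is a stationary point -- and
a minimum -- of the field.

For EDC1 (power-law kernel, eta = 2, unit plastochron) the stationarity
condition ``dI/dtheta = 0`` at the incipient position is solved for the
age-factor parameters ``(a, b)`` under the two possible geometries of the
preceding primordia:

* situation 1 -- the last primordium sits at -90 degrees (divergence
  +/-90), the older ones at +90, 180, 0, ... ;
* situation 2 -- the last primordium sits at 180 (divergence +/-180), the
  older ones at -90, +90, 0, ... .

Parameter pairs satisfying both situations (curve intersections) are the
candidates for stable normal orixate patterning.  For plain DC1 the same
residuals are scanned over ``(eta, G)`` to confirm numerically that no
parameter choice stabilizes the normal orixate arrangement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .geometry import Primordium
from .inhibition import (
    DC1Params,
    DC2Params,
    EDC1Params,
    age_factor_edc1,
    field_dc1,
    field_dc2,
)

__all__ = [
    "ArtificialArrangement",
    "ConditionCurve",
    "IntersectionResult",
    "Landscape",
    "make_normal_orixate",
    "landscape",
    "edc1_stationarity_residual",
    "solve_edc1_condition",
    "find_intersections",
    "dc1_orixate_scan",
]

#: divergence cycle read backward from the incipient primordium, per situation:
#: theta_{n-1}, theta_{n-2}, theta_{n-3}, theta_{n-4} (then repeating).
_BACKWARD_ANGLES = {
    "situation_1": (-90.0, 90.0, 180.0, 0.0),
    "situation_2": (180.0, -90.0, 90.0, 0.0),
}


@dataclass(frozen=True)
class ArtificialArrangement:
    """Prescribed primordium arrangement with the incipient one at 0 degrees.

    ``primordia`` are ordered oldest first, as in a simulation trace; the
    incipient primordium itself is *not* included.  Times are standardized
    and shifted so the incipient primordium would appear at time 0.
    """

    primordia: tuple
    situation: str

    @property
    def thetas(self) -> np.ndarray:
        return np.array([p.theta for p in self.primordia])

    @property
    def birth_times(self) -> np.ndarray:
        return np.array([p.birth_time for p in self.primordia])


def make_normal_orixate(
    n: int,
    plastochrons: tuple = (0.1, 0.325),
    model: str = "dc2",
    situation: str = "situation_1",
) -> ArtificialArrangement:
    """Arrange ``n`` preceding primordia in the normal orixate pattern.

    Angles follow the exact divergence cycle 180, 90, -180, -90 so that the
    positions occupy four orthogonal ranks.  For ``model='dc2'`` the
    standardized plastochron oscillates between the two given values, the
    shorter one between opposite pairs (+/-180 divergence) and the longer
    one between adjacent pairs (+/-90), as observed in orixate shoots.  For
    ``model='dc1'`` every plastochron is one (unit) plastochron.
    """
    if n < 5:
        raise ValueError("need at least five preceding primordia")
    if situation not in _BACKWARD_ANGLES:
        raise ValueError(f"unknown situation {situation!r}")
    short, long_ = sorted(plastochrons)
    base = _BACKWARD_ANGLES[situation]
    prims = []
    t = 0.0
    prev_theta = 0.0
    for age_idx in range(1, n + 1):  # age_idx = n_incipient - m
        theta = base[(age_idx - 1) % 4]
        if model == "dc1":
            t -= 1.0
        else:
            # plastochron between this primordium and its successor; the
            # divergence of that step decides short (opposite) vs long
            # (adjacent)
            div = abs((prev_theta - theta + 180.0) % 360.0 - 180.0)
            t -= short if div > 135.0 else long_
        prims.append((theta, t))
        prev_theta = theta
    prims.reverse()
    primordia = tuple(
        Primordium(i + 1, th, bt) for i, (th, bt) in enumerate(prims)
    )
    return ArtificialArrangement(primordia, situation)


@dataclass(frozen=True)
class Landscape:
    """Field profile on *M* with its local extrema."""

    theta: np.ndarray
    intensity: np.ndarray
    minima: tuple  # (angle, value) pairs
    maxima: tuple


def _local_extrema(theta: np.ndarray, I: np.ndarray):
    """Cyclic local minima and maxima of a sampled profile."""
    left = np.roll(I, 1)
    right = np.roll(I, -1)
    mins = np.where((I < left) & (I <= right))[0]
    maxs = np.where((I > left) & (I >= right))[0]
    return (
        tuple((float(theta[i]), float(I[i])) for i in mins),
        tuple((float(theta[i]), float(I[i])) for i in maxs),
    )


def landscape(
    arr: ArtificialArrangement,
    params,
    now: float = 0.0,
    angle_resolution: float = 0.1,
) -> Landscape:
    """Inhibitory field on *M* generated by a fixed arrangement.

    Dispatches on the parameter record: DC1-family fields use the planar
    power-law kernel with integer plastochron ages; DC2-family fields use
    the threshold kernel at standardized time ``now``.
    """
    grid = np.arange(round(360.0 / angle_resolution)) * angle_resolution
    if isinstance(params, DC1Params):
        n = len(arr.primordia) + 1
        I = field_dc1(grid, arr.primordia, params, n=n)
    elif isinstance(params, DC2Params):
        I = field_dc2(grid, arr.primordia, now, params)
    else:
        raise TypeError(f"unsupported parameter record {type(params).__name__}")
    mins, maxs = _local_extrema(grid, I)
    return Landscape(grid, I, mins, maxs)


# ---------------------------------------------------------------------------
# EDC1 stationarity condition at the incipient orixate position


def _edc1_field_at(theta_deg, ages, thetas, params: DC1Params):
    """EDC1/DC1 field of an artificial arrangement at given angles.

    ``ages`` are plastochron ages (n - m); radii follow ``exp(G * age)``.
    Vectorized over ``theta_deg``.
    """
    th = np.atleast_1d(np.asarray(theta_deg, dtype=float))
    r = np.exp(params.G * ages)
    dphi = np.radians(th[:, None] - thetas[None, :])
    d2 = 1.0 + r * r - 2.0 * r * np.cos(dphi)
    contrib = params.k * d2 ** (-params.eta / 2.0)
    ap = params.age_params
    if ap is not None:
        contrib = contrib * age_factor_edc1(ages, *ap)[None, :]
    return contrib.sum(axis=1)


def edc1_stationarity_residual(
    params: DC1Params,
    situation: str,
    n_preceding: int = 100,
    h: float = 0.01,
    analytic: bool = False,
):
    """``dI/dtheta`` (per radian) at the incipient orixate position.

    The preceding primordia follow the normal orixate arrangement of the
    given situation with unit plastochrons.  The derivative is taken by
    central differences with step ``h`` degrees; ``analytic=True`` instead
    evaluates the closed-form derivative of the power-law field (used as an
    independent cross-check).  Also returns the second derivative estimate
    (per radian squared), whose sign distinguishes minimum from maximum.
    """
    base = _BACKWARD_ANGLES[situation]
    ages = np.arange(1, n_preceding + 1, dtype=float)
    thetas = np.array([base[int(a - 1) % 4] for a in ages])
    if analytic:
        r = np.exp(params.G * ages)
        sin0 = np.sin(np.radians(-thetas))
        d2 = 1.0 + r * r - 2.0 * r * np.cos(np.radians(-thetas))
        # d/dtheta of (1 + r^2 - 2 r cos(theta - theta_m))^(-eta/2) at 0
        terms = (
            params.k
            * (-params.eta / 2.0)
            * d2 ** (-params.eta / 2.0 - 1.0)
            * (2.0 * r * sin0)
        )
        ap = params.age_params
        if ap is not None:
            terms = terms * age_factor_edc1(ages, *ap)
        d1 = float(terms.sum())
        I = _edc1_field_at([h, 0.0, -h], ages, thetas, params)
    else:
        I = _edc1_field_at([h, 0.0, -h], ages, thetas, params)
        d1 = float((I[0] - I[2]) / (2.0 * np.radians(h)))
    d2v = float((I[0] - 2.0 * I[1] + I[2]) / np.radians(h) ** 2)
    return d1, d2v


def _stationarity_weights(
    G: float, situation: str, n_preceding: int = 100, h: float = 0.01
):
    """Per-primordium sensitivities of the angular derivative at 0 degrees.

    The central-difference residual is linear in the age factors:
    ``dI/dtheta(0) = sum_m s_m F(age_m)`` with ``s_m`` depending only on the
    geometry (eta = 2, k = 1).  Returns ``(ages, s)``; precomputing ``s``
    makes scans over (a, b) cheap.
    """
    base = _BACKWARD_ANGLES[situation]
    ages = np.arange(1, n_preceding + 1, dtype=float)
    thetas = np.array([base[int(m - 1) % 4] for m in ages])
    r = np.exp(G * ages)
    th = np.array([h, -h])
    dphi = np.radians(th[:, None] - thetas[None, :])
    d2 = 1.0 + r * r - 2.0 * r * np.cos(dphi)
    c = d2 ** (-1.0)  # eta = 2, k = 1
    sm = (c[0] - c[1]) / (2.0 * np.radians(h))
    return ages, sm


@dataclass(frozen=True)
class ConditionCurve:
    """Solutions ``b(a)`` of the stationarity condition for one situation."""

    G: float
    situation: str
    points: tuple  # (a, b) pairs
    residuals: tuple

    @property
    def a_values(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def b_values(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


def solve_edc1_condition(
    G: float,
    situation: str,
    a_grid=None,
    b_bracket: tuple = (0.0, 20.0),
    n_preceding: int = 100,
    n_scan: int = 400,
) -> ConditionCurve:
    """Solve the EDC1 orixate stationarity condition for ``b`` along ``a``.

    For each ``a`` the residual ``dI/dtheta(0)`` is scanned over the ``b``
    bracket and every sign change is refined by Brent's method, so the
    curve may hold several branches per ``a`` (the residual is nearly
    periodic in ``b`` with the four-step angle cycle).  Grid points without
    a root are omitted.
    """
    if a_grid is None:
        a_grid = np.arange(-20.0, 20.0 + 1e-9, 0.1)
    ages, sm = _stationarity_weights(G, situation, n_preceding)
    pts, resids = [], []
    bs = np.linspace(b_bracket[0], b_bracket[1], n_scan)
    for a in np.asarray(a_grid, dtype=float):
        if a == 0.0:
            continue  # constant age factor: plain DC1, no stationarity

        def res(b):
            return float(np.dot(sm, age_factor_edc1(ages, float(a), float(b))))

        vals = sm @ age_factor_edc1(ages[:, None], a, bs[None, :])
        sign = np.sign(vals)
        for i in np.where(sign[:-1] * sign[1:] < 0)[0]:
            b_root = optimize.brentq(res, bs[i], bs[i + 1], xtol=1e-12, rtol=1e-15)
            pts.append((float(a), float(b_root)))
            resids.append(res(b_root))
    return ConditionCurve(G, situation, tuple(pts), tuple(resids))


@dataclass(frozen=True)
class IntersectionResult:
    """Crossings of the two situation curves at a common ``G``."""

    G: float
    points: tuple  # refined (a, b) pairs
    residuals: tuple  # (res_situation_1, res_situation_2) at each point
    degenerate: bool = False


def find_intersections(
    c1: ConditionCurve, c2: ConditionCurve, n_preceding: int = 100,
    na: int | None = None, nb: int | None = None,
) -> IntersectionResult:
    """Intersect the two situations' condition curves and refine the roots.

    Because each curve can fold and carry several branches in ``b``, the
    crossings are located directly in the ``(a, b)`` plane: both residual
    surfaces are sampled over the bounding box of the curves, cells where
    both change sign seed a two-variable root solve, and converged,
    deduplicated solutions are returned.  If the two curves coincide
    pointwise the result is flagged degenerate.
    """
    if c1.G != c2.G:
        raise ValueError("curves must share the same G")
    if not c1.points or not c2.points:
        return IntersectionResult(c1.G, (), ())
    if len(c1.points) == len(c2.points) and max(
        max(abs(p[0] - q[0]), abs(p[1] - q[1]))
        for p, q in zip(c1.points, c2.points)
    ) < 1e-9:
        res = tuple(_both_residuals(c1.G, a, b, n_preceding) for a, b in c1.points)
        return IntersectionResult(c1.G, c1.points, res, degenerate=True)
    allpts = np.array(list(c1.points) + list(c2.points))
    # margins: crossings can sit just past a curve fold, slightly outside
    # the sampled root range
    a_lo, a_hi = allpts[:, 0].min() - 0.5, allpts[:, 0].max() + 0.2
    b_lo = max(allpts[:, 1].min() - 0.5, 0.05)
    b_hi = allpts[:, 1].max() + 0.5
    if a_hi - a_lo < 1e-9 or b_hi - b_lo < 1e-9:
        return IntersectionResult(c1.G, (), ())
    # cell size must resolve the curves' folds: ~0.02 in a, ~0.1 in b
    if na is None:
        na = max(60, int(np.ceil((a_hi - a_lo) / 0.02)) + 1)
    if nb is None:
        nb = max(80, int(np.ceil((b_hi - b_lo) / 0.1)) + 1)
    As = np.linspace(a_lo, a_hi, na)
    Bs = np.linspace(b_lo, b_hi, nb)
    ages1, s1 = _stationarity_weights(c1.G, "situation_1", n_preceding)
    ages2, s2 = _stationarity_weights(c1.G, "situation_2", n_preceding)
    R1 = np.empty((na, nb))
    R2 = np.empty((na, nb))
    for i, a in enumerate(As):
        F = age_factor_edc1(ages1[:, None], a, Bs[None, :])
        R1[i] = s1 @ F
        R2[i] = s2 @ F

    def both(v):
        return _both_residuals(c1.G, v[0], v[1], n_preceding)

    points, residuals = [], []
    for i in range(na - 1):
        for j in range(nb - 1):
            q1 = R1[i : i + 2, j : j + 2]
            q2 = R2[i : i + 2, j : j + 2]
            if not (q1.min() < 0 < q1.max() and q2.min() < 0 < q2.max()):
                continue
            sol = optimize.root(
                both,
                [0.5 * (As[i] + As[i + 1]), 0.5 * (Bs[j] + Bs[j + 1])],
                method="hybr",
                tol=1e-13,
            )
            if not sol.success:
                continue
            a_s, b_s = float(sol.x[0]), float(sol.x[1])
            if not (a_lo <= a_s <= a_hi and b_lo <= b_s <= b_hi):
                continue
            if any(abs(a_s - p[0]) < 1e-4 and abs(b_s - p[1]) < 1e-4 for p in points):
                continue
            points.append((a_s, b_s))
            residuals.append(tuple(both(sol.x)))
    return IntersectionResult(c1.G, tuple(points), tuple(residuals))


def _both_residuals(G: float, a: float, b: float, n_preceding: int):
    p = EDC1Params(G=G, a=float(a), b=float(b))
    r1 = edc1_stationarity_residual(p, "situation_1", n_preceding)[0]
    r2 = edc1_stationarity_residual(p, "situation_2", n_preceding)[0]
    return (r1, r2)


def dc1_orixate_scan(
    eta_grid=None, G_grid=None, n_preceding: int = 100
) -> pd.DataFrame:
    """Stationarity residuals of plain DC1 over an ``(eta, G)`` grid.

    For each grid point the normal orixate arrangement's residuals in both
    situations are evaluated together with the field curvature at the
    incipient position.  Normal orixate phyllotaxis would require both
    residuals to vanish at a positive-curvature (minimum) point; the scan
    supports its impossibility in DC1 when no grid point achieves that.
    """
    if eta_grid is None:
        eta_grid = np.linspace(1.0, 10.0, 50)
    if G_grid is None:
        G_grid = np.linspace(0.05, 1.0, 50)
    rows = []
    for eta in np.asarray(eta_grid, dtype=float):
        for G in np.asarray(G_grid, dtype=float):
            p = DC1Params(eta=float(eta), G=float(G))
            r1, c1 = edc1_stationarity_residual(p, "situation_1", n_preceding)
            r2, c2 = edc1_stationarity_residual(p, "situation_2", n_preceding)
            rows.append(
                {
                    "eta": eta,
                    "G": G,
                    "residual_situation_1": r1,
                    "residual_situation_2": r2,
                    "curvature_situation_1": c1,
                    "curvature_situation_2": c2,
                }
            )
    return pd.DataFrame(rows)


def write_curves(curves, path) -> None:
    """CSV writer for condition curves: one row per (G, situation, a, b)."""
    rows = [
        {"G": c.G, "situation": c.situation, "a": a, "b": b, "residual": r}
        for c in curves
        for (a, b), r in zip(c.points, c.residuals)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_intersections(results, path) -> None:
    """CSV writer for intersection results."""
    rows = [
        {
            "G": res.G,
            "a": a,
            "b": b,
            "residual_situation_1": r[0],
            "residual_situation_2": r[1],
            "degenerate": res.degenerate,
        }
        for res in results
        for (a, b), r in zip(res.points, res.residuals)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
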