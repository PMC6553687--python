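"""Simulation engines for the four inhibitory-field models.

Two engines:

``run_dc1``
    DC1/EDC1.  One primordium per plastochron; at each iteration the field
    is evaluated on the angular grid and the new primordium is placed at the
    global minimum.

``run_dc2``
    DC2/EDC2.  Continuous standardized time advanced in steps ``dt``; while
    the field minimum on *M* drops below the threshold ``Es`` a primordium
    is inserted immediately at the minimizing grid angle, the field is
    re-evaluated including the newborn (whose divergent self-inhibition
    prevents double insertion), and the sweep repeats -- so several
    primordia may share one birth time (whorls).

Both engines are deterministic.  Grid ties are broken by scanning angles in
increasing order from 0 degrees ('ccw'); the mirrored scan ('cw') yields the
mirror-image trace, as chirality is physically arbitrary.

The DC2 engine prunes primordia whose maximum possible contribution to the
field has decayed below ``prune_tol * Es``; the bound is monotone in age, so
pruned primordia never return.  Set ``prune=False`` for oracle comparisons.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .geometry import Primordium
from .inhibition import (
    _EXP_CAP,
    DC1Params,
    DC2Params,
    EDC1Params,
    EDC2Params,
    age_factor_edc1,
    age_factor_edc2,
    field_dc2_at,
)

__all__ = [
    "SimSettings",
    "SimulationTrace",
    "run_dc1",
    "run_dc2",
    "equivalence_check_edc2_dc2",
    "write_trace",
    "read_trace",
    "contour_matrix",
    "write_contour",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimSettings:
    """Discretization and run-control settings shared by both engines.

    angle_resolution : grid spacing on *M* in degrees (must divide 360).
    dt : standardized time step of the DC2/EDC2 engine.
    max_primordia : total primordium count at which a run stops.
    initial_condition : 'single' (one primordium at 0 degrees) or
        'two_at_120' (two primordia 120 degrees apart), DC2-family only.
    tie_break : 'ccw' scans grid angles upward from 0, 'cw' downward;
        the first global minimum encountered wins.
    prune / prune_tol : drop primordia once their best-case contribution
        falls below ``prune_tol * Es`` (DC2-family engine only).
    max_time : safety cap on simulated time; exceeding it raises, which
        signals a parameter set that never triggers insertion.
    seed : reserved for future stochastic variants; the engines are
        deterministic and ignore it.
    """

    angle_resolution: float = 0.1
    dt: float = 0.001
    max_primordia: int = 100
    initial_condition: str = "single"
    tie_break: str = "ccw"
    prune: bool = True
    prune_tol: float = 1e-12
    max_time: float = 500.0
    seed: int = 0

    def __post_init__(self):
        n = round(360.0 / self.angle_resolution)
        if abs(n * self.angle_resolution - 360.0) > 1e-9 or n < 4:
            raise ValueError("angle_resolution must divide 360")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.max_primordia < 2:
            raise ValueError("max_primordia must be at least 2")
        if self.initial_condition not in ("single", "two_at_120"):
            raise ValueError(f"unknown initial_condition {self.initial_condition!r}")
        if self.tie_break not in ("ccw", "cw"):
            raise ValueError(f"unknown tie_break {self.tie_break!r}")

    @property
    def n_grid(self) -> int:
        return round(360.0 / self.angle_resolution)

    def grid(self) -> np.ndarray:
        return np.arange(self.n_grid) * self.angle_resolution


@dataclass
class InsertionEvent:
    """Per-insertion record: when, where, and how low the field was."""

    time: float
    theta: float
    min_value: float


@dataclass
class SimulationTrace:
    """Ordered record of all primordia from one run plus its settings."""

    primordia: list
    model_tag: str
    params: object
    settings: SimSettings
    event_log: list = field(default_factory=list)

    @property
    def thetas(self) -> np.ndarray:
        return np.array([p.theta for p in self.primordia], dtype=float)

    @property
    def birth_times(self) -> np.ndarray:
        return np.array([p.birth_time for p in self.primordia], dtype=float)

    @property
    def final_time(self) -> float:
        return self.primordia[-1].birth_time if self.primordia else 0.0


def _model_tag(params) -> str:
    if isinstance(params, EDC1Params):
        return "edc1"
    if isinstance(params, DC1Params):
        return "dc1"
    if isinstance(params, EDC2Params):
        return "edc2"
    if isinstance(params, DC2Params):
        return "dc2"
    raise TypeError(f"unrecognized parameter record {type(params).__name__}")


def _symmetric_cos_table(settings: SimSettings) -> np.ndarray:
    """cos of the grid angles, built from the folded index distance.

    Entry ``k`` holds ``cos(res * min(k, n - k))``, which makes the table --
    and every field assembled from it -- exactly symmetric under index
    mirroring, so the two tie-break directions yield bit-exact mirror
    trajectories.
    """
    n = settings.n_grid
    k = np.arange(n)
    return np.cos(np.radians(settings.angle_resolution * np.minimum(k, n - k)))


def _scan_order(n_grid: int, tie_break: str) -> np.ndarray:
    if tie_break == "ccw":
        return np.arange(n_grid)
    # cw: 0 deg, then downward through 360 - res, 360 - 2 res, ...
    return np.concatenate(([0], np.arange(n_grid - 1, 0, -1)))


def run_dc1(params: DC1Params, settings: SimSettings | None = None) -> SimulationTrace:
    """Simulate DC1 (or EDC1 if given :class:`EDC1Params`).

    The first primordium sits at 0 degrees at iteration 1; each subsequent
    iteration adds one primordium at the grid angle minimizing the field.
    Birth times are stored in standardized units (iteration index times one
    plastochron ``G``), so ``ln(r_m / r_{m+1}) = G`` exactly.
    """
    settings = settings or SimSettings()
    tag = _model_tag(params)
    if tag not in ("dc1", "edc1"):
        raise TypeError("run_dc1 needs DC1Params or EDC1Params")
    grid = settings.grid()
    order = _scan_order(settings.n_grid, settings.tie_break)
    cos_sym = _symmetric_cos_table(settings)
    max_p = settings.max_primordia
    # cos(grid - theta_m) per primordium, from index differences so that
    # mirror-image configurations produce bit-identical fields
    cos_rows = np.empty((max_p, settings.n_grid))
    cos_rows[0] = cos_sym  # first primordium at index 0
    primordia = [Primordium(1, 0.0, 0.0)]
    events = [InsertionEvent(0.0, 0.0, np.nan)]
    ap = params.age_params
    for n in range(2, max_p + 1):
        ages = np.arange(n - 1, 0, -1, dtype=float)
        eg = np.exp(params.G * ages)
        denom = (1.0 + eg * eg)[:, None] - (2.0 * eg)[:, None] * cos_rows[: n - 1]
        contrib = params.k * denom ** (-params.eta / 2.0)
        if ap is not None:
            contrib *= age_factor_edc1(ages, *ap)[:, None]
        I = contrib.sum(axis=0)
        idx = order[int(np.argmin(I[order]))]
        cos_rows[n - 1] = np.roll(cos_sym, idx)
        theta = grid[idx]
        primordia.append(Primordium(n, theta, (n - 1) * params.G))
        events.append(InsertionEvent((n - 1) * params.G, theta, float(I[idx])))
    return SimulationTrace(primordia, tag, params, settings, events)


class _DC2Engine:
    """Incremental DC2/EDC2 field evaluation with cached angle rows."""

    def __init__(self, params: DC2Params, settings: SimSettings):
        self.params = params
        self.settings = settings
        self.grid = settings.grid()
        self.order = _scan_order(settings.n_grid, settings.tie_break)
        cap = settings.max_primordia
        self._one_minus_cos = 1.0 - _symmetric_cos_table(settings)
        # 1 - cos(grid - theta_m), one row per primordium (index-based)
        self._omc = np.empty((cap, settings.n_grid))
        self.thetas = np.empty(cap)
        self.births = np.empty(cap)
        self.count = 0
        self.first_active = 0
        self.events: list[InsertionEvent] = []
        ap = params.age_params
        self._age_factor = (
            None if ap is None else (lambda age: age_factor_edc2(age, *ap))
        )

    def _d0(self, t: float) -> float:
        return self.params.gamma_at(t) * self.params.N

    def _d2(self, r, omc):
        # smoothed conical distance squared from a primordium at radius r
        # to the grid circle r = 1 (omc = 1 - cos of the angular offsets)
        N = self.params.N
        dr2 = (1.0 - r) ** 2
        if self.params.distance_variant == "chord":
            return dr2 + (2.0 * N * N * r) * omc
        return N * dr2 + (2.0 * N * r) * omc

    def _dmin(self, r) -> float:
        # closest possible approach to the grid circle, over all angles
        if self.params.distance_variant == "chord":
            return r - 1.0
        return np.sqrt(self.params.N) * (r - 1.0)

    def insert(self, idx: int, t: float, min_value: float) -> None:
        theta = self.grid[idx]
        i = self.count
        self.thetas[i] = theta
        self.births[i] = t
        self._omc[i] = np.roll(self._one_minus_cos, idx)
        self.count += 1
        self.events.append(InsertionEvent(t, float(theta), min_value))

    def contribution_row(self, i: int, t: float) -> np.ndarray:
        """Field contribution of primordium ``i`` alone at time ``t``."""
        p = self.params
        age = t - self.births[i]
        r = np.exp(age)
        d2 = self._d2(r, self._omc[i])
        x2a = np.sqrt(d2) * (2.0 * p.alpha / self._d0(t))
        num = p.Es * np.expm1(2.0 * p.alpha)
        with np.errstate(divide="ignore"):
            row = num / np.expm1(np.minimum(x2a, _EXP_CAP))
        row = np.where(d2 == 0.0, np.inf, row)
        if self._age_factor is not None:
            row = row * self._age_factor(age)
        return row

    def _prune(self, t: float) -> None:
        # upper bound on a primordium's contribution anywhere on M:
        # E evaluated at the closest possible distance sqrt(N) (r - 1),
        # with age factor at most 1; monotone decreasing in age.
        p = self.params
        d0 = self._d0(t)
        num = p.Es * np.expm1(2.0 * p.alpha)
        tol = self.settings.prune_tol * p.Es
        while self.first_active < self.count - 1:
            r = np.exp(t - self.births[self.first_active])
            dmin = self._dmin(r)
            if dmin <= 0:
                break
            bound = num / np.expm1(min(2.0 * p.alpha * dmin / d0, _EXP_CAP))
            if bound < tol:
                self.first_active += 1
            else:
                break

    def field(self, t: float) -> np.ndarray:
        p = self.params
        if self.settings.prune:
            self._prune(t)
        sl = slice(self.first_active, self.count)
        ages = t - self.births[sl]
        r = np.exp(ages)
        d2 = self._d2(r[:, None], self._omc[sl])
        x2a = np.sqrt(d2) * (2.0 * p.alpha / self._d0(t))
        num = p.Es * np.expm1(2.0 * p.alpha)
        with np.errstate(divide="ignore"):
            contrib = num / np.expm1(np.minimum(x2a, _EXP_CAP))
        if np.any(d2 == 0.0):
            contrib = np.where(d2 == 0.0, np.inf, contrib)
        if self._age_factor is not None:
            contrib *= self._age_factor(ages)[:, None]
        return contrib.sum(axis=0)

    def insertion_sweep(self, I: np.ndarray, t: float) -> int:
        """Insert primordia while the field dips below threshold.

        Returns the number inserted; mutates ``I`` in place by adding each
        newborn's contribution.
        """
        Es = self.params.Es
        inserted = 0
        while self.count < self.settings.max_primordia:
            idx = self.order[int(np.argmin(I[self.order]))]
            if not (I[idx] < Es):
                break
            self.insert(idx, t, float(I[idx]))
            inserted += 1
            if inserted > self.settings.max_primordia:
                raise RuntimeError(
                    "runaway insertion: more than max_primordia in one step "
                    "(pathological parameters)"
                )
            I += self.contribution_row(self.count - 1, t)
        return inserted


def run_dc2(params: DC2Params, settings: SimSettings | None = None) -> SimulationTrace:
    """Simulate DC2 (or EDC2 if given :class:`EDC2Params`).

    Starts from the configured initial condition at time 0, advances in
    steps ``dt``, and inserts a primordium at the minimizing grid angle
    whenever the field drops below ``Es``, allowing several insertions per
    step (see module docstring).  Stops once ``max_primordia`` exist.
    """
    settings = settings or SimSettings()
    tag = _model_tag(params)
    if tag not in ("dc2", "edc2"):
        raise TypeError("run_dc2 needs DC2Params or EDC2Params")
    eng = _DC2Engine(params, settings)

    init_angles = [0.0] if settings.initial_condition == "single" else [0.0, 120.0]
    for theta in init_angles:
        idx = int(round(theta / settings.angle_resolution)) % settings.n_grid
        eng.insert(idx, 0.0, np.nan)

    step = 0
    t = 0.0
    I = eng.field(t)
    eng.insertion_sweep(I, t)
    while eng.count < settings.max_primordia:
        step += 1
        t = step * settings.dt
        if t > settings.max_time:
            raise RuntimeError(
                f"no insertion before max_time={settings.max_time}: "
                "field never falls below threshold"
            )
        I = eng.field(t)
        if I.min() < params.Es:
            eng.insertion_sweep(I, t)

    primordia = [
        Primordium(i + 1, eng.thetas[i], eng.births[i]) for i in range(eng.count)
    ]
    logger.debug(
        "run_dc2 finished: %d primordia, %d steps, t=%.3f", eng.count, step, t
    )
    return SimulationTrace(primordia, tag, params, settings, eng.events)


def run(params, settings: SimSettings | None = None) -> SimulationTrace:
    """Dispatch to the engine matching the parameter record."""
    tag = _model_tag(params)
    return run_dc1(params, settings) if tag in ("dc1", "edc1") else run_dc2(
        params, settings
    )


def equivalence_check_edc2_dc2(
    params: DC2Params, settings: SimSettings | None = None
) -> bool:
    """Check that EDC2 with a step-like age factor reproduces plain DC2.

    Runs DC2 and EDC2 (A = 1000, B = 0, same geometry) with identical
    settings and compares the primordium angle sequences to within one grid
    step.  With so steep a logistic, the inhibitory power is effectively
    constant for any positive age, so the two systems should agree except
    at degenerate parameter points.
    """
    settings = settings or SimSettings()
    base = DC2Params(alpha=params.alpha, Gamma=params.Gamma, N=params.N, Es=params.Es)
    stepd = EDC2Params(
        alpha=params.alpha, Gamma=params.Gamma, N=params.N, Es=params.Es,
        A=1000.0, B=0.0,
    )
    tr1 = run_dc2(base, settings)
    tr2 = run_dc2(stepd, settings)
    if len(tr1.primordia) != len(tr2.primordia):
        return False
    d = np.abs(tr1.thetas - tr2.thetas) % 360.0
    d = np.minimum(d, 360.0 - d)
    return bool(np.all(d <= settings.angle_resolution + 1e-12))


# ---------------------------------------------------------------------------
# trace I/O


def write_trace(trace: SimulationTrace, path) -> None:
    """Write a trace as CSV plus a JSON sidecar with params and settings."""
    now = trace.final_time
    rows = []
    for p, ev in zip(trace.primordia, trace.event_log):
        rows.append(
            {
                "index": p.index,
                "birth_time": p.birth_time,
                "theta_deg": p.theta,
                "r_over_R0": float(np.exp(now - p.birth_time)),
                "min_field_at_birth": ev.min_value,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
    sidecar = {
        "model_tag": trace.model_tag,
        "params": _params_dict(trace.params),
        "settings": asdict(trace.settings),
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def _params_dict(params) -> dict:
    d = asdict(params)
    if d.get("ramp") is not None:
        d["ramp"] = asdict(params.ramp)
    return d


def read_trace(path) -> SimulationTrace:
    """Rebuild a trace (and its parameter record) from :func:`write_trace` output."""
    from .inhibition import GammaRamp

    df = pd.read_csv(path)
    with open(str(path) + ".json") as fh:
        sidecar = json.load(fh)
    tag = sidecar["model_tag"]
    pd_ = sidecar["params"]
    if tag == "dc1":
        params = DC1Params(**pd_)
    elif tag == "edc1":
        params = EDC1Params(**pd_)
    elif tag == "dc2":
        params = DC2Params(**pd_)
    else:
        ramp = pd_.pop("ramp", None)
        params = EDC2Params(**pd_, ramp=GammaRamp(**ramp) if ramp else None)
    settings = SimSettings(**sidecar["settings"])
    primordia = [
        Primordium(int(r.index), float(r.theta_deg), float(r.birth_time))
        for r in df.itertuples()
    ]
    events = [
        InsertionEvent(float(r.birth_time), float(r.theta_deg),
                       float(r.min_field_at_birth))
        for r in df.itertuples()
    ]
    return SimulationTrace(primordia, tag, params, settings, events)


# ---------------------------------------------------------------------------
# contour maps of ln I over the apical region


def contour_matrix(
    trace: SimulationTrace,
    now: float | None = None,
    r_max: float = 4.0,
    n_r: int = 200,
    n_theta: int = 360,
):
    """Natural log of the DC2/EDC2 field on an (angle, radius) raster.

    Returns ``(ln_I, r_axis, theta_axis)``; rows follow the radial axis.  A
    value of 0 marks the insertion threshold.
    """
    if trace.model_tag not in ("dc2", "edc2"):
        raise ValueError("contour maps are defined for DC2-family traces")
    now = trace.final_time if now is None else now
    r_axis = np.linspace(r_max / n_r, r_max, n_r)
    theta_axis = np.arange(n_theta) * (360.0 / n_theta)
    R, T = np.meshgrid(r_axis, theta_axis, indexing="ij")
    live = [p for p in trace.primordia if p.birth_time <= now]
    I = field_dc2_at((R.ravel(), T.ravel()), live, now, trace.params)
    with np.errstate(divide="ignore"):
        ln_I = np.log(I).reshape(n_r, n_theta)
    return ln_I, r_axis, theta_axis


def write_contour(trace: SimulationTrace, path_png, path_txt=None, **kwargs) -> None:
    """Render a contour map to PNG (and optionally a plain-text matrix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ln_I, r_axis, theta_axis = contour_matrix(trace, **kwargs)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
    T, R = np.meshgrid(np.radians(theta_axis), r_axis)
    m = ax.pcolormesh(T, R, ln_I, shading="auto", cmap="viridis")
    fig.colorbar(m, ax=ax, label="ln I")
    ax.set_title(f"{trace.model_tag.upper()} inhibitory field (ln I)")
    fig.savefig(path_png, dpi=120)
    plt.close(fig)
    if path_txt is not None:
        np.savetxt(path_txt, ln_I)
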