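"""Divergence-angle series extraction and phyllotactic pattern classification.

A completed simulation trace is summarized by two series -- signed
divergence angles ``theta_{m+1} - theta_m`` wrapped into ``(-180, 180]``
and standardized plastochrons ``t_{m+1} - t_m = ln(r_m / r_{m+1})`` -- and
then classified into the taxonomy used for the sweep maps:

* alternate patterns: regular (constant divergence), two-cycle, tetrastichous
  four-cycle (divergence sequence ``p, q, -p, -q``), or an x-cycle (one
  ~180-degree step followed by ``x - 1`` near-zero steps);
* whorled patterns: decussate (pairs rotated ~90 degrees), tricussate
  (triplets rotated ~60 degrees), other whorled;
* anything else: ``other``.

Stability is judged on the trailing window of the trace (by default the
last nine primordia for alternate patterns and the last two nodes for
whorled ones); a detected cycle must repeat at least twice inside the
window.  Each class maps to an HSL color: hue runs from cyan (0 degrees
divergence) to red (180), saturation encodes the small-to-large ratio of
successive |divergence angles| (1 = full saturation) and lightness the
small-to-large plastochron ratio (0 = full lightness).
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import wrap_180

__all__ = [
    "DivergenceSeries",
    "PatternClass",
    "ColorCode",
    "divergence_series",
    "group_nodes",
    "classify",
    "color_encode",
    "ratio_stats",
    "classification_report",
]

CATEGORIES = (
    "regular_alternate",
    "two_cycle_alternate",
    "four_cycle_alternate",
    "x_cycle_alternate",
    "decussate",
    "tricussate",
    "other_whorled",
    "other",
)


@dataclass(frozen=True)
class DivergenceSeries:
    """Per-pair divergence angles (signed degrees) and plastochrons."""

    angles: np.ndarray
    plastochrons: np.ndarray


@dataclass(frozen=True)
class PatternClass:
    """Taxonomy label plus the quantitative descriptors behind it."""

    category: str
    cycle_length: int | None = None
    representative_angles: tuple | None = None
    mean_divergence: float | None = None
    angle_ratio: float | None = None
    plastochron_ratio: float | None = None
    primordia_per_node: int | None = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass(frozen=True)
class ColorCode:
    """HSL triple in [0, 1] encoding a :class:`PatternClass`."""

    hue: float
    saturation: float
    lightness: float

    def __post_init__(self):
        for name in ("hue", "saturation", "lightness"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} out of range: {v}")

    def to_rgb(self) -> tuple:
        return colorsys.hls_to_rgb(self.hue, self.lightness, self.saturation)


def divergence_series(trace) -> DivergenceSeries:
    """Signed divergence angles and plastochrons of consecutive primordia."""
    if len(trace.primordia) < 2:
        raise ValueError("need at least two primordia")
    angles = wrap_180(np.diff(trace.thetas))
    plastochrons = np.diff(trace.birth_times)
    return DivergenceSeries(np.atleast_1d(angles), plastochrons)


def group_nodes(trace) -> list:
    """Partition primordia into nodes: members share one insertion time.

    DC2-family runs may insert several primordia in a single time step
    (a whorl); DC1-family traces always yield singleton nodes.
    """
    nodes: list[list] = []
    last_t = None
    for p in trace.primordia:
        if last_t is not None and p.birth_time == last_t:
            nodes[-1].append(p)
        else:
            nodes.append([p])
            last_t = p.birth_time
    return nodes


# -- helpers -----------------------------------------------------------------


def _phase_means_abs(values: np.ndarray, c: int) -> np.ndarray:
    """Mean |value| per cycle phase, phases counted from the series end."""
    out = np.empty(c)
    for k in range(c):
        out[k] = np.mean(np.abs(values[len(values) - c + k :: -c][::-1]))
    return out


def _is_periodic(angles: np.ndarray, c: int, tol: float) -> bool:
    if len(angles) < 2 * c:
        return False
    diff = wrap_180(angles[c:] - angles[:-c])
    return bool(np.all(np.abs(diff) <= tol))


def _ratio(a: float, b: float) -> float:
    hi = max(abs(a), abs(b))
    return 1.0 if hi == 0 else min(abs(a), abs(b)) / hi


def _node_axis_rotation(node1, node2, k: int) -> float:
    """Angular rotation between two k-member whorls, folded into [0, 360/k)."""
    period = 360.0 / k
    a1 = np.sort(np.array([p.theta for p in node1]) % period)
    a2 = np.sort(np.array([p.theta for p in node2]) % period)
    rot = (np.mean(a2) - np.mean(a1)) % period
    return min(rot, period - rot)


def _classify_whorled(nodes, whorl_tol: float) -> PatternClass:
    n1, n2 = nodes[-2], nodes[-1]
    k1, k2 = len(n1), len(n2)
    if k1 != k2:
        return PatternClass("other")
    if k1 == 2:
        rot = _node_axis_rotation(n1, n2, 2)
        if abs(rot - 90.0) <= whorl_tol:
            return PatternClass("decussate", primordia_per_node=2)
        return PatternClass("other_whorled", primordia_per_node=2)
    if k1 == 3:
        rot = _node_axis_rotation(n1, n2, 3)
        if abs(rot - 60.0) <= whorl_tol:
            return PatternClass("tricussate", primordia_per_node=3)
        return PatternClass("other_whorled", primordia_per_node=3)
    return PatternClass("other_whorled", primordia_per_node=k1)


def _match_x_cycle(angles: np.ndarray, c: int, x_tol: float):
    """Detect a motif of one ~180-degree step and c-1 near-zero steps."""
    if len(angles) < 2 * c:
        return None
    is180 = np.abs(np.abs(angles) - 180.0) < x_tol
    is0 = np.abs(angles) < x_tol
    if not np.all(is180 | is0):
        return None
    pos = np.where(is180)[0]
    if len(pos) == 0:
        return None
    if not np.all(np.diff(pos) == c):
        return None
    # trailing/leading partial periods must also be consistent with period c
    if pos[0] >= c or (len(angles) - 1 - pos[-1]) >= c:
        return None
    return pos


def classify(
    trace,
    window: int = 9,
    angle_tol: float = 2.0,
    x_tol: float = 10.0,
    whorl_tol: float = 10.0,
    x_window: int = 30,
) -> PatternClass:
    """Classify the stabilized end of a trace into the pattern taxonomy.

    The last ``window`` primordia (``window - 1`` divergence angles) decide
    alternate patterns; the last two nodes decide whorled ones.  x-cycle
    detection widens to the last ``x_window`` angles because a long cycle
    cannot repeat twice inside the default window.

    Parameters
    ----------
    angle_tol : degrees within which two divergence angles count as equal.
    x_tol : half-width of the ~0 and ~180 degree bins of x-cycle motifs.
    whorl_tol : tolerance on the 90/60 degree inter-whorl rotation.
    """
    if len(trace.primordia) < window:
        raise ValueError(f"trace shorter than window={window}")
    nodes = group_nodes(trace)
    if len(nodes) >= 2 and (len(nodes[-1]) > 1 or len(nodes[-2]) > 1):
        return _classify_whorled(nodes, whorl_tol)

    series = divergence_series(trace)
    angles = series.angles[-(window - 1) :]
    plast = series.plastochrons[-(window - 1) :]

    for c in (1, 2, 4):
        if not _is_periodic(angles, c, angle_tol):
            continue
        ph_ang = _phase_means_abs(angles, c)
        ph_pl = _phase_means_abs(plast, c) if len(plast) >= 2 * c else np.array([1.0])
        if c == 1:
            return PatternClass(
                "regular_alternate",
                cycle_length=1,
                representative_angles=(float(ph_ang[0]),),
                mean_divergence=float(ph_ang[0]),
                angle_ratio=1.0,
                plastochron_ratio=_ratio(ph_pl.min(), ph_pl.max()),
            )
        if c == 2:
            return PatternClass(
                "two_cycle_alternate",
                cycle_length=2,
                representative_angles=tuple(np.round(ph_ang, 6)),
                mean_divergence=float(ph_ang.mean()),
                angle_ratio=_ratio(ph_ang[0], ph_ang[1]),
                plastochron_ratio=_ratio(ph_pl.min(), ph_pl.max()),
            )
        # c == 4: the tetrastichous signature is (p, q, -p, -q)
        tail = angles[-4:]
        if (
            abs(wrap_180(tail[0] + tail[2])) <= angle_tol
            and abs(wrap_180(tail[1] + tail[3])) <= angle_tol
        ):
            p_abs, q_abs = max(ph_ang[2], ph_ang[3]), min(ph_ang[2], ph_ang[3])
            return PatternClass(
                "four_cycle_alternate",
                cycle_length=4,
                representative_angles=tuple(np.round(ph_ang, 6)),
                mean_divergence=float(ph_ang.mean()),
                angle_ratio=q_abs / p_abs if p_abs else 1.0,
                plastochron_ratio=_ratio(ph_pl.min(), ph_pl.max()),
            )
        break

    wide = series.angles[-x_window:]
    wide_pl = series.plastochrons[-x_window:]
    for c in range(2, 9):
        pos = _match_x_cycle(wide, c, x_tol)
        if pos is not None:
            return PatternClass(
                "x_cycle_alternate",
                cycle_length=c,
                representative_angles=(180.0,) + (0.0,) * (c - 1),
                mean_divergence=float(np.mean(np.abs(wide))),
                angle_ratio=None,
                plastochron_ratio=_ratio(wide_pl.min(), wide_pl.max()),
            )
    return PatternClass("other")


# reserved colors for the non-alternate branches of the legend
_RESERVED = {
    "decussate": (0.75, 1.0, 0.5),
    "tricussate": (0.88, 1.0, 0.5),
    "other_whorled": (0.0, 0.0, 0.25),
    "x_cycle_alternate": (0.0, 0.0, 0.0),
    "other": (0.0, 0.0, 0.7),
}


def color_encode(pc: PatternClass) -> ColorCode:
    """Map a classified pattern to its legend color (HSL components).

    Alternate patterns: hue interpolates linearly from cyan at 0 degrees
    mean divergence to red at 180; saturation equals the angle ratio (full
    saturation at 1); lightness interpolates from full lightness at
    plastochron ratio 0 to the pure hue at ratio 1.  Whorled classes,
    x-cycles, and ``other`` use fixed reserved colors.
    """
    if pc.category in _RESERVED:
        h, s, l = _RESERVED[pc.category]
        return ColorCode(h, s, l)
    mean = min(abs(pc.mean_divergence or 0.0), 180.0)
    hue = 0.5 * (1.0 - mean / 180.0)
    sat = pc.angle_ratio if pc.angle_ratio is not None else 1.0
    pr = pc.plastochron_ratio if pc.plastochron_ratio is not None else 1.0
    lightness = 1.0 - 0.5 * pr
    return ColorCode(hue, sat, lightness)


def ratio_stats(pc: PatternClass) -> tuple:
    """(angle ratio, plastochron ratio) of an oscillating alternate pattern.

    Defined only for two-cycle and four-cycle patterns; these are the axes
    used to compare simulated patterns against measured orixate shoots.
    """
    if pc.category not in ("two_cycle_alternate", "four_cycle_alternate"):
        raise ValueError(f"ratio_stats undefined for category {pc.category!r}")
    return (pc.angle_ratio, pc.plastochron_ratio)


def classification_report(rows: list, path=None) -> pd.DataFrame:
    """Tabulate (label, PatternClass) pairs; optionally write CSV."""
    recs = []
    for label, pc in rows:
        color = color_encode(pc)
        recs.append(
            {
                "label": label,
                "category": pc.category,
                "cycle_length": pc.cycle_length,
                "representative_angles": (
                    "" if pc.representative_angles is None
                    else ";".join(f"{a:.2f}" for a in pc.representative_angles)
                ),
                "mean_divergence": pc.mean_divergence,
                "angle_ratio": pc.angle_ratio,
                "plastochron_ratio": pc.plastochron_ratio,
                "primordia_per_node": pc.primordia_per_node,
                "hue": color.hue,
                "saturation": color.saturation,
                "lightness": color.lightness,
            }
        )
    df = pd.DataFrame(recs)
    if path is not None:
        df.to_csv(path, index=False)
    return df
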