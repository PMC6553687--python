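"""Parameter sweeps: classify every grid point and render the color map.

A sweep runs one of the four models over a 1- or 2-axis parameter grid,
classifies each resulting pattern, and encodes it with the legend colors,
reproducing the published bifurcation panels at configurable density.  Rows
are mutually independent, so evaluation order cannot change the result; a
failed simulation (e.g. runaway insertion) flags its row and the sweep
continues.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .analysis import classify, color_encode
from .inhibition import DC1Params, DC2Params, EDC1Params, EDC2Params
from .simulate import SimSettings, run

__all__ = ["SweepAxis", "SweepGrid", "SweepResult", "run_sweep", "render_map"]

logger = logging.getLogger(__name__)

_PARAM_TYPES = {
    "dc1": DC1Params,
    "edc1": EDC1Params,
    "dc2": DC2Params,
    "edc2": EDC2Params,
}


@dataclass(frozen=True)
class SweepAxis:
    """One swept parameter: name plus an inclusive linear range."""

    name: str
    start: float
    stop: float
    count: int

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("axis count must be positive")

    def values(self) -> np.ndarray:
        if self.count == 1:
            return np.array([self.start])
        return np.linspace(self.start, self.stop, self.count)


@dataclass(frozen=True)
class SweepGrid:
    """Sweep specification: model, 1-2 axes, fixed parameters, settings."""

    model_tag: str
    axes: tuple
    fixed: dict = field(default_factory=dict)
    settings: SimSettings = field(default_factory=SimSettings)
    scale: float = 1.0  # grid-density factor relative to the reference panels

    def __post_init__(self):
        if self.model_tag not in _PARAM_TYPES:
            raise ValueError(f"unknown model_tag {self.model_tag!r}")
        if not (1 <= len(self.axes) <= 2):
            raise ValueError("sweeps support one or two axes")
        valid = _PARAM_TYPES[self.model_tag].__dataclass_fields__
        for ax in self.axes:
            if ax.name not in valid:
                raise ValueError(
                    f"parameter {ax.name!r} not valid for {self.model_tag}"
                )

    @classmethod
    def from_config(cls, cfg: dict) -> "SweepGrid":
        axes = tuple(SweepAxis(**ax) for ax in cfg["axes"])
        settings = SimSettings(**cfg.get("settings", {}))
        return cls(
            model_tag=cfg["model_tag"],
            axes=axes,
            fixed=dict(cfg.get("fixed", {})),
            settings=settings,
            scale=cfg.get("scale", 1.0),
        )


@dataclass
class SweepResult:
    """One classified row per grid point plus provenance for re-runs."""

    grid: SweepGrid
    table: pd.DataFrame
    provenance: dict


def _grid_points(grid: SweepGrid):
    if len(grid.axes) == 1:
        for v in grid.axes[0].values():
            yield {grid.axes[0].name: float(v)}
    else:
        ax0, ax1 = grid.axes
        for v1 in ax1.values():
            for v0 in ax0.values():
                yield {ax0.name: float(v0), ax1.name: float(v1)}


def run_sweep(grid: SweepGrid, window: int = 9) -> SweepResult:
    """Simulate, classify and color-encode every grid point."""
    cls = _PARAM_TYPES[grid.model_tag]
    rows = []
    t0 = time.perf_counter()
    for point in _grid_points(grid):
        row = dict(point)
        try:
            params = cls(**{**grid.fixed, **point})
            trace = run(params, grid.settings)
            pc = classify(trace, window=window)
            color = color_encode(pc)
            row.update(
                category=pc.category,
                cycle_length=pc.cycle_length,
                mean_divergence=pc.mean_divergence,
                angle_ratio=pc.angle_ratio,
                plastochron_ratio=pc.plastochron_ratio,
                hue=color.hue,
                saturation=color.saturation,
                lightness=color.lightness,
                error="",
            )
        except Exception as exc:  # noqa: BLE001 - row-level fault isolation
            logger.warning("sweep point %s failed: %s", point, exc)
            row.update(
                category="error",
                cycle_length=None,
                mean_divergence=None,
                angle_ratio=None,
                plastochron_ratio=None,
                hue=None,
                saturation=None,
                lightness=None,
                error=str(exc),
            )
        rows.append(row)
    provenance = {
        "model_tag": grid.model_tag,
        "axes": [asdict(ax) for ax in grid.axes],
        "fixed": dict(grid.fixed),
        "settings": asdict(grid.settings),
        "scale": grid.scale,
        "wall_time_s": time.perf_counter() - t0,
        "n_points": len(rows),
    }
    return SweepResult(grid, pd.DataFrame(rows), provenance)


def render_map(result: SweepResult, path=None) -> np.ndarray:
    """Rasterize a 2-axis sweep into an RGB image (one pixel per point).

    Rows follow the second axis bottom-to-top, columns the first axis
    left-to-right; failed rows render black.  Returns the image array and
    optionally writes an annotated PNG.
    """
    grid = result.grid
    if len(grid.axes) != 2:
        raise ValueError("render_map needs a 2-axis sweep; plot 1-axis profiles instead")
    ax0, ax1 = grid.axes
    img = np.zeros((ax1.count, ax0.count, 3))
    from .analysis import ColorCode

    for k, row in result.table.iterrows():
        i, j = divmod(k, ax0.count)
        if row["category"] == "error" or row["hue"] is None or np.isnan(row["hue"]):
            continue
        img[i, j] = ColorCode(row["hue"], row["saturation"], row["lightness"]).to_rgb()
    if path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        ax.imshow(
            img,
            origin="lower",
            aspect="auto",
            extent=(ax0.start, ax0.stop, ax1.start, ax1.stop),
        )
        ax.set_xlabel(ax0.name)
        ax.set_ylabel(ax1.name)
        ax.set_title(f"{grid.model_tag.upper()} sweep")
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return img
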