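"""Folding x binding fitness landscapes by nearest-neighbour interpolation.

Axes are min-max normalised to [0, 1] before the nearest-neighbour search so
that the kcal/mol and Angstrom scales contribute equally; each grid cell
takes the fitness of the nearest data point, ties broken by lowest input
index.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class LandscapeGrid:
    x: np.ndarray  # ddG axis (kcal/mol), length nx
    y: np.ndarray  # distance axis (A), length ny
    values: np.ndarray  # (ny, nx) interpolated fitness
    nearest_index: np.ndarray  # (ny, nx) index of the source data point
    x_range: tuple[float, float]
    y_range: tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.y, name="dist_active"),
                            columns=pd.Index(self.x, name="ddG"))

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def _normalise(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    span = hi - lo
    if span == 0:  # degenerate axis: all points collapse to 0
        return np.zeros_like(v, dtype=float)
    return (v - lo) / span


def build_grid(
    ddg: np.ndarray,
    dist: np.ndarray,
    fitness: np.ndarray,
    resolution: int = 100,
    chunk: int = 2048,
) -> LandscapeGrid:
    """Nearest-neighbour fitness grid over the (ddG, distance) plane.

    Grid bounds span the data; distances are Euclidean in min-max normalised
    coordinates.  Brute-force argmin guarantees the lowest-index tie rule.
    """
    ddg = np.asarray(ddg, dtype=float)
    dist = np.asarray(dist, dtype=float)
    fitness = np.asarray(fitness, dtype=float)
    ok = np.isfinite(ddg) & np.isfinite(dist) & np.isfinite(fitness)
    ddg, dist, fitness = ddg[ok], dist[ok], fitness[ok]
    if len(ddg) < 1:
        raise ValueError("no usable data points")
    x_range = (float(ddg.min()), float(ddg.max()))
    y_range = (float(dist.min()), float(dist.max()))
    x = np.linspace(*x_range, resolution)
    y = np.linspace(*y_range, resolution)
    px = _normalise(ddg, *x_range)
    py = _normalise(dist, *y_range)
    gx = _normalise(x, *x_range)
    gy = _normalise(y, *y_range)
    xx, yy = np.meshgrid(gx, gy)
    cells = np.column_stack([xx.ravel(), yy.ravel()])
    points = np.column_stack([px, py])
    nearest = np.empty(len(cells), dtype=np.int64)
    for start in range(0, len(cells), chunk):
        block = cells[start : start + chunk]
        d2 = ((block[:, None, :] - points[None, :, :]) ** 2).sum(axis=2)
        nearest[start : start + chunk] = d2.argmin(axis=1)  # argmin -> lowest index ties
    values = fitness[nearest].reshape(resolution, resolution)
    return LandscapeGrid(
        x=x, y=y, values=values,
        nearest_index=nearest.reshape(resolution, resolution),
        x_range=x_range, y_range=y_range,
    )


def build_grid_from_table(
    table: pd.DataFrame,
    features: pd.DataFrame,
    resolution: int = 100,
) -> LandscapeGrid:
    """Grid from a FitnessTable joined to ddG/dist_active features (survivors only)."""
    key = ["position", "wt", "mut"]
    surv = table[table["survived"].astype(bool)]
    joined = surv[key + ["F"]].merge(features[key + ["ddG", "dist_active"]], on=key)
    joined = joined.dropna(subset=["F", "ddG", "dist_active"])
    if len(joined) < 3:
        raise ValueError("need >= 3 mutants with fitness and both features")
    return build_grid(
        joined["ddG"].to_numpy(), joined["dist_active"].to_numpy(),
        joined["F"].to_numpy(), resolution=resolution,
    )


def gradient_field(grid: LandscapeGrid) -> tuple[np.ndarray, np.ndarray]:
    """dF/dx, dF/dy over the grid (optional export; points toward maxima)."""
    dy, dx = np.gradient(grid.values, grid.y, grid.x)
    return dx, dy


def render(
    grids: dict[str, LandscapeGrid],
    outdir: str | Path,
    vmin: float | None = None,
    vmax: float | None = None,
    levels: int = 20,
    fmt: str = "png",
) -> dict[str, Path]:
    """Render contour plots with a colour scale shared across the batch."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if vmin is None:
        vmin = min(float(np.nanmin(g.values)) for g in grids.values())
    if vmax is None:
        vmax = max(float(np.nanmax(g.values)) for g in grids.values())
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, grid in grids.items():
        fig, ax = plt.subplots(figsize=(5, 4))
        cs = ax.contourf(
            grid.x, grid.y, grid.values,
            levels=np.linspace(vmin, vmax, levels), vmin=vmin, vmax=vmax, cmap="viridis",
            extend="both",
        )
        fig.colorbar(cs, ax=ax, label="fitness (log2)")
        ax.set_xlabel("ddG (kcal/mol)")
        ax.set_ylabel("distance from active site (A)")
        ax.set_title(name)
        path = outdir / f"landscape_{name}.{fmt}"
        fig.savefig(path, dpi=150, metadata={"Software": "dmsenv"} if fmt == "png" else None)
        plt.close(fig)
        paths[name] = path
    return paths
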