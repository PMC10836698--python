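"""The three ensemble-regression figures.

* beta-range forest plot — per (domain, predictor): a bar spanning the
  extreme point estimates, whiskers spanning the outermost CI limits, and a
  black tick at the pooled estimate;
* bootstrap ridgeline plot — per outcome lane, one kernel-density curve per
  predictor over the bootstrap betas;
* bootstrap violin plot — the same densities mirrored into violin glyphs,
  dodged within outcome groups.

Rendering is deterministic: identical inputs and options produce
byte-identical SVG output.  Every glyph carries a ``gid`` of the form
``band:<domain>:<predictor>`` / ``density:...`` / ``violin:...`` so figure
structure can be inspected programmatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from matplotlib import rc_context
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure
from matplotlib.lines import Line2D
from matplotlib.patches import Rectangle
from scipy.stats import gaussian_kde

from .errors import PlotError

#: Okabe-Ito colorblind-safe qualitative palette, assigned to predictors in
#: first-appearance order.
PALETTE = [
    "#E69F00",
    "#56B4E9",
    "#009E73",
    "#F0E442",
    "#0072B2",
    "#D55E00",
    "#CC79A7",
    "#999999",
]

_DETERMINISTIC_RC = {"svg.hashsalt": "betaforest"}
_SAVE_METADATA = {
    ".svg": {"metadata": {"Date": None}},
    ".pdf": {"metadata": {"CreationDate": None}},
    ".png": {},
}


@dataclass
class PlotOptions:
    """Shared appearance options for all three figures."""

    null_line_x: float = 0.0
    benchmark_lines: Sequence[float] = (-0.5, -0.3, -0.1, 0.1, 0.3, 0.5)
    color_by: str = "predictor"
    width: float = 9.0
    height: float = 6.0
    dpi: int = 300
    x_limits: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        bl = [float(b) for b in self.benchmark_lines]
        if not all(np.isfinite(bl)):
            raise ValueError("benchmark lines must be finite")
        if bl != sorted(bl):
            raise ValueError("benchmark lines must be sorted ascending")
        self.benchmark_lines = tuple(bl)
        if self.width <= 0 or self.height <= 0:
            raise ValueError("figure dimensions must be positive")
        if self.color_by not in ("predictor", "domain"):
            raise ValueError("color_by must be 'predictor' or 'domain'")


def density_curve(values: np.ndarray, gridsize: int = 256, cut: float = 3.0):
    """Gaussian KDE (Silverman bandwidth) of a 1-d sample on a regular grid.

    Shared by the ridgeline and violin renderers so both draw the same
    density estimate.  Requires at least two distinct values.
    """
    values = np.asarray(values, dtype=float)
    if len(np.unique(values)) < 2:
        raise ValueError("need at least 2 distinct values for a density estimate")
    kde = gaussian_kde(values, bw_method="silverman")
    bw = float(kde.factor * values.std(ddof=1))
    grid = np.linspace(values.min() - cut * bw, values.max() + cut * bw, gridsize)
    return grid, kde(grid)


def _save(fig: Figure, out_path: str, dpi: int) -> None:
    suffix = "." + str(out_path).rsplit(".", 1)[-1].lower() if "." in str(out_path) else ""
    if suffix not in (".png", ".svg", ".pdf"):
        raise PlotError(f"unsupported output format {suffix!r}: use png, svg or pdf")
    with rc_context(_DETERMINISTIC_RC):
        fig.savefig(out_path, dpi=dpi, **_SAVE_METADATA[suffix])


def _new_axes(options: PlotOptions):
    fig = Figure(figsize=(options.width, options.height))
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(111)
    return fig, ax


def _color_map(keys: Sequence[str]) -> dict:
    return {k: PALETTE[i % len(PALETTE)] for i, k in enumerate(keys)}


def _reference_lines(ax, options: PlotOptions, axis: str = "x") -> None:
    line = ax.axvline if axis == "x" else ax.axhline
    null = line(options.null_line_x, color="red", linewidth=1.2, zorder=1)
    null.set_gid("null-line")
    lo, hi = (-np.inf, np.inf) if options.x_limits is None else options.x_limits
    for b in options.benchmark_lines:
        if lo <= b <= hi:
            ref = line(b, color="0.4", linewidth=0.8, linestyle=":", zorder=1)
            ref.set_gid("benchmark-line")


def _legend(ax, color_of: dict, title: str) -> None:
    handles = [Line2D([], [], color=c, linewidth=4, label=k) for k, c in color_of.items()]
    ax.legend(handles=handles, title=title, loc="center left", bbox_to_anchor=(1.01, 0.5), frameon=False)


def plot_beta_range_forest(ranges: pd.DataFrame, options: PlotOptions, out_path: str) -> Figure:
    """Render the beta-range forest plot and write it to ``out_path``.

    One horizontal band per input row: a filled rectangle over
    [est_min, est_max], whiskers over [ci_outer_lower, ci_outer_upper] and a
    black tick at beta_pooled.  Domains stack along the y-axis with
    predictor bands dodged within each domain.
    """
    if len(ranges) == 0:
        raise PlotError("cannot plot an empty beta-range table")
    bad = ranges[ranges["est_min"] > ranges["est_max"]]
    if len(bad):
        cells = list(zip(bad["domain"], bad["predictor"]))
        raise PlotError(f"est_min > est_max for cells: {cells}")

    domains = list(ranges["domain"].unique())
    predictors = list(ranges["predictor"].unique())
    color_of = _color_map(predictors)
    n_pred = len(predictors)
    offsets = np.linspace(0.35, -0.35, n_pred) if n_pred > 1 else np.array([0.0])
    band_h = 0.6 / max(n_pred, 1)

    fig, ax = _new_axes(options)
    _reference_lines(ax, options, axis="x")
    for row in ranges.itertuples():
        y = -domains.index(row.domain) + offsets[predictors.index(row.predictor)]
        color = color_of[row.predictor]
        whisker = Line2D(
            [row.ci_outer_lower, row.ci_outer_upper], [y, y], color=color, linewidth=1.0, zorder=2
        )
        whisker.set_gid(f"whisker:{row.domain}:{row.predictor}")
        ax.add_line(whisker)
        band = Rectangle(
            (row.est_min, y - band_h / 2),
            row.est_max - row.est_min,
            band_h,
            facecolor=color,
            edgecolor=color,
            linewidth=1.0,
            zorder=3,
        )
        band.set_gid(f"band:{row.domain}:{row.predictor}")
        ax.add_patch(band)
        tick = Line2D(
            [row.beta_pooled, row.beta_pooled],
            [y - band_h / 2, y + band_h / 2],
            color="black",
            linewidth=1.4,
            zorder=4,
        )
        tick.set_gid(f"pooled-tick:{row.domain}:{row.predictor}")
        ax.add_line(tick)

    ax.set_yticks([-i for i in range(len(domains))], domains)
    ax.set_ylim(-len(domains) + 0.5, 0.5)
    if options.x_limits is not None:
        ax.set_xlim(*options.x_limits)
    ax.set_xlabel("Standardized coefficient (beta)")
    _legend(ax, color_of, "Predictor")
    fig.tight_layout()
    _save(fig, out_path, options.dpi)
    return fig


def _cell_densities(draws: pd.DataFrame):
    """Per-(outcome, predictor) density curves; errors name the failing cell."""
    curves = {}
    for (outcome, predictor), cell in draws.groupby(["outcome", "predictor"], sort=False):
        try:
            curves[(outcome, predictor)] = density_curve(cell["beta"].to_numpy())
        except ValueError as exc:
            raise PlotError(f"cell ({predictor}, {outcome}): {exc}") from None
    return curves


def plot_bootstrap_ridgeline(draws: pd.DataFrame, options: PlotOptions, out_path: str) -> Figure:
    """Render the bootstrap ridgeline plot: one lane per outcome, one
    density curve per predictor within the lane."""
    if len(draws) == 0:
        raise PlotError("cannot plot an empty bootstrap table")
    outcomes = list(draws["outcome"].unique())
    predictors = list(draws["predictor"].unique())
    color_of = _color_map(predictors)
    curves = _cell_densities(draws)
    peak = max(dens.max() for _, dens in curves.values())
    scale = 0.85 / peak

    fig, ax = _new_axes(options)
    _reference_lines(ax, options, axis="x")
    for (outcome, predictor), (grid, dens) in curves.items():
        base = -outcomes.index(outcome)
        color = color_of[predictor]
        poly = ax.fill_between(grid, base, base + dens * scale, facecolor=color, alpha=0.55, zorder=2)
        poly.set_gid(f"density:{outcome}:{predictor}")
        outline = Line2D(grid, base + dens * scale, color=color, linewidth=0.8, zorder=3)
        ax.add_line(outline)

    ax.set_yticks([-i for i in range(len(outcomes))], outcomes)
    ax.set_ylim(-len(outcomes) + 0.5, 1.0)
    if options.x_limits is not None:
        ax.set_xlim(*options.x_limits)
    ax.set_xlabel("Standardized coefficient (beta)")
    _legend(ax, color_of, "Predictor")
    fig.tight_layout()
    _save(fig, out_path, options.dpi)
    return fig


def plot_bootstrap_violin(draws: pd.DataFrame, options: PlotOptions, out_path: str) -> Figure:
    """Render the bootstrap violin plot: outcome groups along the x-axis,
    one mirrored-density glyph per predictor dodged within each group; beta
    on the y-axis (reference lines are horizontal here)."""
    if len(draws) == 0:
        raise PlotError("cannot plot an empty bootstrap table")
    outcomes = list(draws["outcome"].unique())
    predictors = list(draws["predictor"].unique())
    color_of = _color_map(predictors)
    curves = _cell_densities(draws)
    n_pred = len(predictors)
    offsets = (
        np.linspace(-0.4 + 0.4 / n_pred, 0.4 - 0.4 / n_pred, n_pred) if n_pred > 1 else np.array([0.0])
    )
    half_width = 0.36 / max(n_pred, 1)

    fig, ax = _new_axes(options)
    _reference_lines(ax, options, axis="y")
    for (outcome, predictor), (grid, dens) in curves.items():
        center = outcomes.index(outcome) + offsets[predictors.index(predictor)]
        color = color_of[predictor]
        shape = dens / dens.max() * half_width
        poly = ax.fill_betweenx(grid, center - shape, center + shape, facecolor=color, alpha=0.75, zorder=2)
        poly.set_gid(f"violin:{outcome}:{predictor}")

    ax.set_xticks(range(len(outcomes)), outcomes, rotation=45, ha="right")
    ax.set_xlim(-0.6, len(outcomes) - 0.4)
    if options.x_limits is not None:
        ax.set_ylim(*options.x_limits)
    ax.set_ylabel("Standardized coefficient (beta)")
    _legend(ax, color_of, "Predictor")
    fig.tight_layout()
    _save(fig, out_path, options.dpi)
    return fig


def count_glyphs(fig: Figure, prefix: str) -> int:
    """Count artists in a figure whose gid starts with ``prefix:`` (or equals
    ``prefix``).  Used by structural tests and sanity checks."""
    count = 0
    for ax in fig.axes:
        for artist in ax.get_children():
            gid = artist.get_gid()
            if gid is not None and (gid == prefix or gid.startswith(prefix + ":")):
                count += 1
    return count
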