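"""Connectograms and worm plots for edgewise association results.

Layout computation is pure and deterministic, separated from matplotlib
rendering so the geometry, colors and orderings are directly testable.

Connectogram: regions sit on a circle, left-hemisphere regions on the left
half, grouped by anatomical cluster and alphabetical by abbreviation within
a cluster. Significant edges are chords: red for positive associations
(or male > female), blue for negative (female > male), with color intensity
increasing in significance. Node opacity is proportional to the node's
count of significant edges, normalized by the maximum, with a floor so
unconnected regions stay legible.

Worm plot: each point is one edge; lanes are anatomical group pairs ordered
by their mean signed association in the ALPACA table; within a lane points
are sorted by association, producing the worm shape. The y value is
-log10(p) * sign(beta) * scale, where each method's scale factor places the
significance threshold of every method on the same pair of horizontal lines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .atlas import GROUPS, RegionAtlas
from .stats import CorrectionResult

NODE_OPACITY_FLOOR = 0.2
#: p-values below alpha_corr / 10**INTENSITY_DECADES render at full intensity
INTENSITY_DECADES = 4.0

POSITIVE_COLOR = (0.85, 0.11, 0.14)  # red
NEGATIVE_COLOR = (0.13, 0.31, 0.76)  # blue


class VizError(ValueError):
    pass


@dataclass
class ConnectogramLayout:
    nodes: list[str]                       # region keys, drawing order
    angles: dict[str, float]               # radians
    node_opacity: dict[str, float]
    edges: list[dict]                      # region_a, region_b, color, intensity, sign

    def __post_init__(self) -> None:
        if len(set(self.angles.values())) != len(self.nodes):
            raise VizError("node angles must be unique")


@dataclass
class WormPlotLayout:
    lanes: list[str]                       # group-pair order (shared x axis)
    points: pd.DataFrame                   # method, lane, lane_rank, y, edge cols
    scales: dict[str, float]
    threshold_y: float                     # lines at +/- threshold_y


def _node_order(atlas: RegionAtlas) -> list[str]:
    """L hemisphere then R, grouped by cluster, alphabetical within."""
    order = []
    for hemi in ("L", "R"):
        for group in GROUPS:
            members = sorted(
                r.key for r in atlas.regions if r.hemisphere == hemi and r.group == group
            )
            order.extend(members)
    return order


def edge_intensity(p: float, alpha_corr: float) -> float:
    """Color intensity in (0, 1], linear in -log10(p) above the threshold.

    p = alpha_corr maps near 0 (just significant); intensity saturates at
    p = alpha_corr / 10**INTENSITY_DECADES.
    """
    ratio = math.log10(alpha_corr) - math.log10(max(p, 1e-300))
    return float(np.clip(ratio / INTENSITY_DECADES, 0.05, 1.0))


def connectogram_layout(
    sig: pd.DataFrame, atlas: RegionAtlas, alpha_corr: float
) -> ConnectogramLayout:
    """Deterministic circular layout of the significant edge set.

    ``sig`` follows the schema of :func:`alpaca_cwas.stats.significant_edges`
    (region_a, region_b, p, sign).
    """
    nodes = _node_order(atlas)
    n = len(nodes)
    angles = {}
    for i, key in enumerate(nodes):
        # left hemisphere occupies the left half-circle (90 -> 270 degrees)
        angles[key] = math.pi / 2 + 2 * math.pi * (i + 0.5) / n

    counts = {key: 0 for key in nodes}
    edges = []
    for _, row in sig.iterrows():
        for key in (row["region_a"], row["region_b"]):
            if key not in counts:
                raise VizError(f"edge references region {key} not in atlas")
            counts[key] += 1
        sign = int(row["sign"])
        edges.append(
            {
                "region_a": row["region_a"],
                "region_b": row["region_b"],
                "sign": sign,
                "color": POSITIVE_COLOR if sign > 0 else NEGATIVE_COLOR,
                "intensity": edge_intensity(float(row["p"]), alpha_corr),
            }
        )
    max_count = max(counts.values()) if counts else 0
    opacity = {
        key: NODE_OPACITY_FLOOR
        + (1 - NODE_OPACITY_FLOOR) * (c / max_count if max_count else 0.0)
        for key, c in counts.items()
    }
    return ConnectogramLayout(nodes=nodes, angles=angles, node_opacity=opacity, edges=edges)


def worm_layout(
    tables: Mapping[str, pd.DataFrame],
    corrections: Mapping[str, CorrectionResult],
    atlas: RegionAtlas,
    covariate: str = "age",
    reference_method: str = "alpaca",
) -> WormPlotLayout:
    """Worm-plot geometry for both connectivity definitions at once.

    Every method's threshold is mapped onto the reference method's, so a
    single pair of dashed lines at +/- C (C = -log10 of the reference
    alpha_corr) marks significance for all methods.
    """
    if reference_method not in tables:
        raise VizError(f"reference method {reference_method!r} missing from tables")
    pcol, bcol = f"p_{covariate}", f"beta_{covariate}"

    edge_sets = {
        m: set(zip(t["region_a"], t["region_b"])) for m, t in tables.items()
    }
    ref_edges = edge_sets[reference_method]
    for m, es in edge_sets.items():
        if es != ref_edges:
            diff = sorted(es.symmetric_difference(ref_edges))
            raise VizError(f"edge sets differ between methods ({m}): {diff[:10]}")

    C = -math.log10(corrections[reference_method].alpha_corr)
    scales = {
        m: C / (-math.log10(corrections[m].alpha_corr)) for m in tables
    }

    group_of = {r.key: r.group for r in atlas.regions}

    def group_pair(table_row) -> str:
        return "/".join(
            sorted([group_of[table_row["region_a"]], group_of[table_row["region_b"]]])
        )

    # lane order: mean signed association in the reference (ALPACA) table
    ref = tables[reference_method]
    ref_assoc = -np.log10(ref[pcol].to_numpy(float)) * np.sign(ref[bcol].to_numpy(float))
    ref_lanes = ref.apply(group_pair, axis=1)
    lane_means = (
        pd.DataFrame({"lane": ref_lanes, "assoc": ref_assoc})
        .groupby("lane")["assoc"]
        .mean()
        .sort_values()
    )
    lanes = list(lane_means.index)

    frames = []
    for m, t in tables.items():
        y = -np.log10(t[pcol].to_numpy(float)) * np.sign(t[bcol].to_numpy(float))
        y = y * scales[m]
        df = pd.DataFrame(
            {
                "method": m,
                "region_a": t["region_a"],
                "region_b": t["region_b"],
                "lane": t.apply(group_pair, axis=1),
                "y": y,
            }
        )
        df["lane_rank"] = df.groupby("lane")["y"].rank(method="first").astype(int) - 1
        frames.append(df)
    points = pd.concat(frames, ignore_index=True)
    return WormPlotLayout(lanes=lanes, points=points, scales=scales, threshold_y=C)


# ---------------------------------------------------------------------------
# rendering


def _stable_svg_rcparams() -> None:
    plt.rcParams["svg.hashsalt"] = "alpaca-cwas"


def render_connectogram(layout: ConnectogramLayout, outfile: Path, title: str = "") -> Path:
    """Draw the connectogram to SVG or PNG. Chords are quadratic Beziers
    through the circle center region; every edge carries a ``gid`` so the
    SVG element count is verifiable."""
    _stable_svg_rcparams()
    fig, ax = plt.subplots(figsize=(7, 7))
    ax.set_aspect("equal")
    ax.axis("off")
    R = 1.0
    for key in layout.nodes:
        th = layout.angles[key]
        x, y = R * math.cos(th), R * math.sin(th)
        ax.plot(
            [x], [y], "o", color="k", alpha=layout.node_opacity[key], markersize=6,
            gid=f"node-{key}",
        )
        ax.annotate(
            key,
            (1.12 * x, 1.12 * y),
            fontsize=5,
            ha="center",
            va="center",
            rotation=0,
        )
    from matplotlib.path import Path as MplPath
    import matplotlib.patches as mpatches

    for k, e in enumerate(layout.edges):
        th_a = layout.angles[e["region_a"]]
        th_b = layout.angles[e["region_b"]]
        pa = (R * math.cos(th_a), R * math.sin(th_a))
        pb = (R * math.cos(th_b), R * math.sin(th_b))
        path = MplPath(
            [pa, (0.0, 0.0), pb],
            [MplPath.MOVETO, MplPath.CURVE3, MplPath.CURVE3],
        )
        patch = mpatches.PathPatch(
            path,
            facecolor="none",
            edgecolor=e["color"],
            alpha=e["intensity"],
            linewidth=1.2,
            gid=f"edge-{k}",
        )
        ax.add_patch(patch)
    if title:
        ax.set_title(title)
    ax.set_xlim(-1.4, 1.4)
    ax.set_ylim(-1.4, 1.4)
    return _save(fig, outfile)


def render_worm(layout: WormPlotLayout, outfile: Path, title: str = "") -> Path:
    """Draw the worm plot; one marker series per method, dashed threshold
    lines at +/- the shared significance level."""
    _stable_svg_rcparams()
    fig, ax = plt.subplots(figsize=(9, 4))
    lane_pos = {lane: i for i, lane in enumerate(layout.lanes)}
    markers = {"alpaca": "o", "meants": "s"}
    lane_width = 0.8
    for m, df in layout.points.groupby("method"):
        xs, ys = [], []
        for lane, sub in df.groupby("lane"):
            k = len(sub)
            offs = (sub["lane_rank"].to_numpy() + 0.5) / k - 0.5
            xs.extend(lane_pos[lane] + lane_width * offs)
            ys.extend(sub["y"].to_numpy())
        ax.plot(
            xs, ys, markers.get(m, "."), markersize=3, alpha=0.7, label=m,
            linestyle="none", gid=f"worm-{m}",
        )
    for sgn in (+1, -1):
        ax.axhline(sgn * layout.threshold_y, linestyle="--", color="gray", linewidth=0.8)
    ax.set_xticks(range(len(layout.lanes)))
    ax.set_xticklabels(layout.lanes, rotation=45, ha="right", fontsize=7)
    ax.set_ylabel("signed scaled $-\\log_{10} p$")
    ax.legend(fontsize=7)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    return _save(fig, outfile)


def _save(fig, outfile: Path) -> Path:
    outfile = Path(outfile)
    outfile.parent.mkdir(parents=True, exist_ok=True)
    try:
        fig.savefig(outfile, metadata={"Date": None} if outfile.suffix == ".svg" else None)
    except OSError as exc:
        raise OSError(f"could not write figure to {outfile}: {exc}") from exc
    finally:
        plt.close(fig)
    return outfile
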