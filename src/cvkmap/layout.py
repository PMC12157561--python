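"""Coordinate assignment for van Krevelen maps, Cartesian and polar.

The defining property of these maps is that every compound has a *fixed*
coordinate computed from its formula alone: H:C on the x-axis (Cartesian)
or as the angle (polar), and O:C or the mass-weighted NOPS:C ratio on the
y-axis / radius.  Because the coordinate is a pure function of the ratios
and the :class:`LayoutConfig`, any two maps drawn with the same config
place a compound at the same point — the consistency that makes the maps
exchangeable between datasets and groups.

The polar angle is a linear map of [0, hc_max] onto [0, 2*pi): with the
default full scale hc_max = 4 (saturated CH4), theta = 2*pi*hc/4 measured
counterclockwise from east.  H:C above the full scale saturates at the
full-scale angle and is flagged rather than wrapped, so distinct compounds
are never aliased by wrapping.

Isomers (cohabitant compounds) share a formula and hence a coordinate;
:func:`resolve_overlaps` separates such collision clusters by a
deterministic symmetric angular fan that preserves every radius, so the
radial coordinate keeps its chemical meaning exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .chem import RatioSet
from .pathway import PathwayGraph

__all__ = [
    "LayoutConfig",
    "LayoutResult",
    "bounding_circle",
    "cartesian_layout",
    "polar_layout",
    "polar_position",
    "resolve_overlaps",
    "write_layout",
]

TWO_PI = 2.0 * math.pi

#: Relative safety margin applied to the separation gap so that resolved
#: pairwise distances clear the threshold despite rounding.
_GAP_MARGIN = 1e-9


@dataclass(frozen=True)
class LayoutConfig:
    """Parameters of the coordinate system and collision resolution.

    Parameters
    ----------
    y_ratio : {"nops", "oc"}
        Which ratio drives the y-axis (Cartesian) or radius (polar).
    hc_max : float
        Angular full scale: H:C = hc_max maps to a full turn.  Default 4.0
        (saturated CH4); a fixed, data-independent scale is what makes
        coordinates comparable across maps.
    r_max : float, optional
        Radial clip.  Radii above it are clipped and flagged; also fixes
        the outer boundary circle.  When unset the boundary is data-driven.
    theta_origin : float
        Angle of H:C = 0 in radians (default 0, east).
    direction : {1, -1}
        +1 for counterclockwise increase of H:C (mathematical convention).
    min_sep : float
        Minimum node separation for collision resolution, as a fraction of
        the outer radius.  Default 0.01.
    max_iter : int
        Iteration cap for collision resolution.
    seed : int
        Reserved for stochastic resolution strategies; the built-in fan is
        deterministic and ignores it.
    """

    y_ratio: str = "nops"
    hc_max: float = 4.0
    r_max: float | None = None
    theta_origin: float = 0.0
    direction: int = 1
    min_sep: float = 0.01
    max_iter: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.y_ratio not in ("nops", "oc"):
            raise ValueError("y_ratio must be 'nops' or 'oc'")
        if not self.hc_max > 0:
            raise ValueError("hc_max must be positive")
        if self.r_max is not None and not self.r_max > 0:
            raise ValueError("r_max must be positive when set")
        if self.direction not in (1, -1):
            raise ValueError("direction must be +1 (ccw) or -1 (cw)")
        if self.min_sep < 0:
            raise ValueError("min_sep must be nonnegative")
        if self.max_iter < 0:
            raise ValueError("max_iter must be nonnegative")

    def selected_ratio(self, ratios: RatioSet) -> float:
        return ratios.nops_c if self.y_ratio == "nops" else ratios.oc


_COLUMNS = [
    "formula",
    "hc",
    "ratio",
    "theta",
    "r",
    "x",
    "y",
    "clipped",
    "hc_saturated",
    "displaced",
    "displacement",
]


@dataclass
class LayoutResult:
    """Per-compound coordinates plus displacement/clipping bookkeeping.

    ``table`` is indexed by compound id (sorted) with columns formula, hc,
    ratio, theta, r, x, y, clipped, hc_saturated, displaced, displacement.
    In Cartesian mode theta and r are NaN.
    """

    mode: str  # "cartesian" | "polar"
    config: LayoutConfig
    table: pd.DataFrame
    residual_collisions: int = 0

    def coordinates(self, compound_id: str) -> tuple[float, float]:
        row = self.table.loc[compound_id]
        return float(row["x"]), float(row["y"])

    @property
    def compound_ids(self) -> list[str]:
        return list(self.table.index)

    def copy(self) -> "LayoutResult":
        return LayoutResult(
            mode=self.mode,
            config=self.config,
            table=self.table.copy(),
            residual_collisions=self.residual_collisions,
        )

    def to_table(self) -> pd.DataFrame:
        """Export table with the stable public column set."""
        out = self.table.reset_index(names="compound_id")
        out = out.rename(columns={"ratio": "selected_ratio", "theta": "theta_rad"})
        return out[
            [
                "compound_id",
                "formula",
                "hc",
                "selected_ratio",
                "theta_rad",
                "r",
                "x",
                "y",
                "displaced",
                "clipped",
            ]
        ]

    def write(self, path: str | Path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)


def write_layout(layout: LayoutResult, path: str | Path) -> None:
    """Write the layout export table (TSV, full floating precision)."""
    layout.write(path)


def polar_position(ratios: RatioSet, config: LayoutConfig) -> tuple[float, float]:
    """Pure polar coordinate of one compound: (theta in [0, 2*pi), radius).

    Independent of any other compound — this function *is* the fixed-
    coordinate guarantee.  The radius is returned unclipped.
    """
    frac = min(ratios.hc, config.hc_max) / config.hc_max
    theta = (config.theta_origin + config.direction * TWO_PI * frac) % TWO_PI
    if theta >= TWO_PI:  # fp guard at the seam
        theta -= TWO_PI
    return theta, config.selected_ratio(ratios)


def _base_frame(graph: PathwayGraph, config: LayoutConfig) -> pd.DataFrame:
    records = []
    for comp in graph.compounds:  # sorted by id
        records.append(
            {
                "compound_id": comp.id,
                "formula": comp.formula,
                "hc": comp.ratios.hc,
                "ratio": config.selected_ratio(comp.ratios),
            }
        )
    df = pd.DataFrame(
        records, columns=["compound_id", "formula", "hc", "ratio"]
    ).set_index("compound_id")
    return df


def cartesian_layout(graph: PathwayGraph, config: LayoutConfig | None = None) -> LayoutResult:
    """Classic van Krevelen scatter: x = H:C, y = selected ratio."""
    config = config or LayoutConfig()
    df = _base_frame(graph, config)
    df["theta"] = np.nan
    df["r"] = np.nan
    df["x"] = df["hc"]
    df["y"] = df["ratio"]
    df["clipped"] = False
    df["hc_saturated"] = False
    df["displaced"] = False
    df["displacement"] = 0.0
    return LayoutResult(mode="cartesian", config=config, table=df[_COLUMNS])


def polar_layout(graph: PathwayGraph, config: LayoutConfig | None = None) -> LayoutResult:
    """Circular van Krevelen layout: H:C as angle, selected ratio as radius."""
    config = config or LayoutConfig()
    df = _base_frame(graph, config)
    thetas, radii, clipped, saturated = [], [], [], []
    for comp in graph.compounds:
        theta, r = polar_position(comp.ratios, config)
        is_clipped = config.r_max is not None and r > config.r_max
        if is_clipped:
            r = config.r_max
        thetas.append(theta)
        radii.append(r)
        clipped.append(is_clipped)
        saturated.append(comp.ratios.hc > config.hc_max)
    df["theta"] = thetas
    df["r"] = radii
    df["x"] = df["r"] * np.cos(df["theta"])
    df["y"] = df["r"] * np.sin(df["theta"])
    df["clipped"] = clipped
    df["hc_saturated"] = saturated
    df["displaced"] = False
    df["displacement"] = 0.0
    return LayoutResult(mode="polar", config=config, table=df[_COLUMNS])


def _effective_rmax(layout: LayoutResult) -> float:
    if layout.config.r_max is not None:
        return layout.config.r_max
    col = "r" if layout.mode == "polar" else "ratio"
    values = layout.table[col].to_numpy(dtype=float)
    return float(np.max(values)) if len(values) else 0.0


def bounding_circle(layout: LayoutResult) -> float:
    """Outer boundary radius: configured r_max, else the maximum radius."""
    if len(layout.table) == 0:
        raise ValueError("bounding_circle of an empty layout")
    return _effective_rmax(layout)


def _collision_clusters(xy: np.ndarray, threshold: float) -> list[np.ndarray]:
    """Index groups of mutually reachable nodes closer than `threshold`."""
    n = len(xy)
    if n < 2 or threshold <= 0:
        return []
    close = squareform(pdist(xy)) < threshold
    np.fill_diagonal(close, False)
    n_comp, labels = connected_components(csr_matrix(close), directed=False)
    clusters = []
    for c in range(n_comp):
        members = np.flatnonzero(labels == c)
        if len(members) > 1:
            clusters.append(members)
    return clusters


def _count_collisions(xy: np.ndarray, threshold: float) -> int:
    if len(xy) < 2 or threshold <= 0:
        return 0
    d = pdist(xy)
    return int(np.sum(d < threshold))


def _circular_mean(angles: np.ndarray) -> float:
    return math.atan2(float(np.mean(np.sin(angles))), float(np.mean(np.cos(angles)))) % TWO_PI


def resolve_overlaps(
    layout: LayoutResult, config: LayoutConfig | None = None
) -> LayoutResult:
    """Separate collision clusters with a deterministic symmetric fan.

    Nodes closer than ``min_sep * r_max`` are grouped into clusters
    (transitive closure of the pairwise test) and fanned out symmetrically
    around their shared angle in lexicographic compound-id order, keeping
    every radius exactly — only the angle moves, so the radial coordinate
    retains its chemical meaning.  The fan gap is sized so adjacent nodes
    sit at least the threshold apart (chord at the cluster's smallest
    radius); a coincident pair ends up at +-gap/2 around the original
    angle, its angular midpoint unchanged.  For k coincident nodes the
    worst-case per-node displacement is ceil((k-1)/2) fan gaps.

    Untouched nodes keep bit-identical coordinates.  The pass repeats up to
    ``max_iter`` times; clusters at radius ~0 cannot be separated
    angularly and remain as residual collisions, counted (with any other
    leftovers) in ``residual_collisions`` — never fatal.

    In Cartesian mode the fan displaces x instead of the angle, preserving
    y the same way.
    """
    config = config or layout.config
    out = layout.copy()
    out.config = config
    df = out.table
    threshold = config.min_sep * _effective_rmax(out)
    if threshold <= 0 or len(df) < 2:
        out.residual_collisions = 0
        return out

    original_xy = df[["x", "y"]].to_numpy(dtype=float).copy()
    gap = threshold * (1.0 + _GAP_MARGIN)

    for _ in range(config.max_iter):
        xy = df[["x", "y"]].to_numpy(dtype=float)
        clusters = _collision_clusters(xy, threshold)
        if not clusters:
            break
        moved = False
        for members in clusters:
            members = np.array(sorted(members, key=lambda i: df.index[i]))
            k = len(members)
            offsets = (np.arange(k) - (k - 1) / 2.0)
            if layout.mode == "polar":
                radii = df["r"].to_numpy(dtype=float)[members]
                r_min = float(np.min(radii))
                if r_min <= gap / 2.0:
                    continue  # angular displacement cannot separate; residual
                dphi = 2.0 * math.asin(min(1.0, gap / (2.0 * r_min)))
                base = _circular_mean(df["theta"].to_numpy(dtype=float)[members])
                new_theta = (base + offsets * dphi) % TWO_PI
                idx = df.index[members]
                df.loc[idx, "theta"] = new_theta
                df.loc[idx, "x"] = radii * np.cos(new_theta)
                df.loc[idx, "y"] = radii * np.sin(new_theta)
            else:
                base_x = float(np.mean(df["x"].to_numpy(dtype=float)[members]))
                idx = df.index[members]
                df.loc[idx, "x"] = base_x + offsets * gap
            df.loc[df.index[members], "displaced"] = True
            moved = True
        if not moved:
            break

    xy = df[["x", "y"]].to_numpy(dtype=float)
    disp = np.linalg.norm(xy - original_xy, axis=1)
    df["displacement"] = np.where(df["displaced"].to_numpy(), disp, 0.0)
    out.residual_collisions = _count_collisions(xy, threshold)
    return out
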