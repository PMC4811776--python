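"""Hierarchical-strength metrics, quadratic vertex fits, network screens.

Hierarchical strength of a region is its average efferent minus average
afferent fixed-connection strength over rostral/caudal edges only —
dorsal/ventral connections between regions at the same level are ignored,
and (by default) negative connections are zeroed before averaging, since
their meaning in this contrast is unclear.  A quadratic fit of strength
against rostral/caudal (MNI y) position summarizes the hierarchy: the
vertex position locates the apex and the vertex height quantifies it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .regions import DEFAULT_EDGES, DEFAULT_GEOMETRY, RegionGeometry

__all__ = [
    "RegionGeometry",
    "HierarchyProfile",
    "VertexFit",
    "NetworkScreenResult",
    "hierarchical_strength",
    "vertex_fit",
    "connectivity_strength_controls",
    "cost_threshold_screen",
    "vertex_group_inference",
]


@dataclass
class VertexFit:
    """Quadratic summary h(y) = b0 + b1 y + b2 y^2 of a strength profile."""

    coefficients: np.ndarray  # (b2, b1, b0) as returned by polyfit
    position: float | None  # y* = -b1 / (2 b2), mm
    height: float | None  # h(y*), Hz
    curvature: float  # b2
    degenerate: bool


@dataclass
class HierarchyProfile:
    """Per-region hierarchical strength plus its quadratic vertex."""

    strength: pd.Series
    vertex: VertexFit
    average_strength: pd.Series | None = None
    total_strength: pd.Series | None = None


def _rc_neighbors(
    geometry: RegionGeometry, edges: tuple[tuple[str, str], ...]
) -> dict[str, list[str]]:
    rc = geometry.rostral_caudal_edges(edges)
    nbrs: dict[str, list[str]] = {r: [] for r in geometry.labels}
    for a, b in rc:
        nbrs[a].append(b)
        nbrs[b].append(a)
    return nbrs


def _prepared(A: np.ndarray, geometry: RegionGeometry, zero_negatives: bool) -> tuple[np.ndarray, np.ndarray]:
    """Working copy of A plus a presence mask.

    Entries that are exactly zero are treated as absent connections and do
    not enter the averages; negative entries are present and (optionally)
    zeroed before averaging.
    """
    A = np.asarray(A, dtype=float)
    n = len(geometry.labels)
    if A.shape != (n, n):
        raise ValueError(f"A must be {(n, n)} to match the geometry")
    W = A.copy()
    np.fill_diagonal(W, 0.0)
    present = W != 0.0
    if zero_negatives:
        W = np.where(W < 0, 0.0, W)
    return W, present


def _mean_present(values: list[float], mask: list[bool]) -> float:
    vals = [v for v, m in zip(values, mask) if m]
    return float(np.mean(vals)) if vals else 0.0


def hierarchical_strength(
    A: np.ndarray,
    geometry: RegionGeometry = DEFAULT_GEOMETRY,
    edges: tuple[tuple[str, str], ...] = DEFAULT_EDGES,
    zero_negatives: bool = True,
) -> pd.Series:
    """Average efferent minus average afferent strength per region (Hz).

    Only rostral/caudal edges count; ``A[i, j]`` is read as the influence
    of region j on region i.  Means run over the region's present
    connections (exact zeros are absent); regions with no rostral/caudal
    edge get NaN.
    """
    W, present = _prepared(A, geometry, zero_negatives)
    nbrs = _rc_neighbors(geometry, edges)
    out = {}
    for r in geometry.labels:
        ri = geometry.index(r)
        targets = nbrs[r]
        if not targets:
            out[r] = np.nan
            continue
        ti = [geometry.index(t) for t in targets]
        eff = _mean_present([W[t, ri] for t in ti], [present[t, ri] for t in ti])
        aff = _mean_present([W[ri, t] for t in ti], [present[ri, t] for t in ti])
        out[r] = eff - aff
    return pd.Series(out, name="hierarchical_strength")


def connectivity_strength_controls(
    A: np.ndarray,
    geometry: RegionGeometry = DEFAULT_GEOMETRY,
    edges: tuple[tuple[str, str], ...] = DEFAULT_EDGES,
    zero_negatives: bool = True,
) -> pd.DataFrame:
    """Average and total rostral/caudal connectivity per region (both
    directions pooled over present connections) — magnitude controls for
    the hierarchy contrast."""
    W, present = _prepared(A, geometry, zero_negatives)
    nbrs = _rc_neighbors(geometry, edges)
    rows = {}
    for r in geometry.labels:
        ri = geometry.index(r)
        targets = nbrs[r]
        if not targets:
            rows[r] = (np.nan, np.nan)
            continue
        ti = [geometry.index(t) for t in targets]
        vals = [W[t, ri] for t in ti if present[t, ri]] + [W[ri, t] for t in ti if present[ri, t]]
        if not vals:
            rows[r] = (0.0, 0.0)
            continue
        rows[r] = (float(np.mean(vals)), float(np.sum(vals)))
    return pd.DataFrame.from_dict(rows, orient="index", columns=["average", "total"])


def vertex_fit(
    strengths: pd.Series | np.ndarray,
    geometry: RegionGeometry = DEFAULT_GEOMETRY,
    curvature_tol: float = 1e-12,
) -> VertexFit:
    """Least-squares quadratic of hierarchical strength on MNI y position.

    Degenerate fits (|curvature| below tolerance, e.g. all-zero or strictly
    linear profiles) are flagged and carry no vertex.
    """
    if isinstance(strengths, pd.Series):
        labels = list(strengths.index)
        h = strengths.to_numpy(dtype=float)
    else:
        labels = list(geometry.labels)
        h = np.asarray(strengths, dtype=float)
    y = np.array([geometry.y(r) for r in labels], dtype=float)
    keep = np.isfinite(h)
    y, h = y[keep], h[keep]
    if np.unique(y).size < 3:
        raise ValueError("vertex fit needs at least 3 distinct y positions")
    coef = np.polyfit(y, h, 2)
    b2, b1, _ = coef
    scale = max(1.0, float(np.max(np.abs(h))) if h.size else 1.0)
    if abs(b2) < curvature_tol * scale:
        return VertexFit(coef, None, None, float(b2), True)
    pos = -b1 / (2.0 * b2)
    height = float(np.polyval(coef, pos))
    return VertexFit(coef, float(pos), height, float(b2), False)


def hierarchy_profile(
    A: np.ndarray,
    geometry: RegionGeometry = DEFAULT_GEOMETRY,
    edges: tuple[tuple[str, str], ...] = DEFAULT_EDGES,
    zero_negatives: bool = True,
) -> HierarchyProfile:
    """Strength, controls and vertex summary for one fixed-connectivity matrix."""
    strength = hierarchical_strength(A, geometry, edges, zero_negatives)
    controls = connectivity_strength_controls(A, geometry, edges, zero_negatives)
    vert = vertex_fit(strength, geometry)
    return HierarchyProfile(
        strength=strength,
        vertex=vert,
        average_strength=controls["average"],
        total_strength=controls["total"],
    )


def vertex_group_inference(
    profiles: list[HierarchyProfile],
    geometry: RegionGeometry = DEFAULT_GEOMETRY,
    rostral: str = "FPl",
    caudal: str = "SFS",
) -> pd.DataFrame:
    """Group tests on the vertex: height > 0, and position against the
    rostral-most and caudal-most ROI y-coordinates."""
    heights = np.array([p.vertex.height for p in profiles if not p.vertex.degenerate])
    positions = np.array([p.vertex.position for p in profiles if not p.vertex.degenerate])
    if heights.size < 3:
        raise ValueError("group vertex inference needs at least 3 non-degenerate fits")
    rows = []
    t, p = stats.ttest_1samp(heights, 0.0)
    rows.append(("height_vs_0", heights.mean(), t, p))
    for name, ref in (("position_vs_" + rostral, geometry.y(rostral)), ("position_vs_" + caudal, geometry.y(caudal))):
        t, p = stats.ttest_1samp(positions, ref)
        rows.append((name, positions.mean() - ref, t, p))
    return pd.DataFrame(rows, columns=["test", "mean", "t", "p"]).set_index("test")


@dataclass
class NetworkScreenResult:
    """ROI membership booleans over a grid of cost thresholds (%)."""

    membership: pd.DataFrame  # index (roi, region), columns = costs
    costs: tuple[float, ...]

    def members_at(self, cost: float) -> pd.Series:
        return self.membership[cost]


def cost_threshold_screen(
    connectivity_values: dict[str, np.ndarray],
    candidate_values: dict[str, dict[str, float]],
    costs=(18.0,),
) -> NetworkScreenResult:
    """Percentile screen for network membership.

    A candidate region belongs to an ROI's network at cost c when its
    connectivity value falls within the top c% of the ROI's reference
    connectivity distribution (i.e. at or above the (100-c)th percentile).
    Membership is monotone non-decreasing in cost.
    """
    costs = tuple(float(c) for c in costs)
    if not costs or any(not (0.0 < c <= 100.0) for c in costs):
        raise ValueError("costs must lie in (0, 100]")
    rows = []
    index = []
    for roi, values in connectivity_values.items():
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            raise ValueError(f"empty connectivity distribution for ROI {roi!r}")
        thresholds = {
            c: (-np.inf if c >= 100.0 else np.percentile(values, 100.0 - c)) for c in costs
        }
        for region, val in candidate_values.get(roi, {}).items():
            rows.append([bool(val >= thresholds[c]) for c in costs])
            index.append((roi, region))
    membership = pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["roi", "region"]), columns=costs
    )
    return NetworkScreenResult(membership=membership, costs=costs)
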