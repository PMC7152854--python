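"""Cluster geometry: alpha-shape hulls, densities, composition, radial profiles.

The concave hull of a cluster is its alpha shape: the union of Delaunay
simplices (triangles in 2D, tetrahedra in 3D) whose circumradius does not
exceed ``alpha``.  As ``alpha → ∞`` this reduces to the convex hull.  The
"auto" setting picks the *critical alpha* — the smallest value at which every
input point is a vertex of at least one retained simplex and the retained
simplices form a single facet-connected region — emulating the
all-points-enclosing defaults of common alpha-shape tools while avoiding the
interior holes that point coverage alone permits on uniformly sampled
clusters.

Hull measures are reported in µm² (2D) or µm³ (3D); molecular densities in
µm^−2 / µm^−3; equivalent diameters (of the disk/sphere with the cluster's
measure) in nm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, Delaunay, QhullError, cKDTree

from .cluster import NOISE, ClusterLabeling
from .errors import GeometryError, InputError

__all__ = [
    "AlphaShapeHull",
    "alpha_shape",
    "cluster_stats",
    "corona_composition",
    "radial_profile",
    "RadialProfile",
]

NM3_PER_UM3 = 1e9
NM2_PER_UM2 = 1e6


@dataclass
class AlphaShapeHull:
    """Alpha-shape of a point cluster.

    ``simplices`` indexes ``points``; ``measure`` is the summed simplex
    measure in µm^d; ``boundary`` holds the facets bounding the shape (those
    appearing in exactly one retained simplex).
    """

    points: np.ndarray
    simplices: np.ndarray
    alpha: float
    measure: float
    boundary: np.ndarray
    circumradii: np.ndarray

    @property
    def ndim(self) -> int:
        return self.points.shape[1]


def _simplex_circumradii(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumradius of each simplex; inf for degenerate simplices."""
    p0 = points[simplices[:, 0]]  # (m, d)
    rest = points[simplices[:, 1:]]  # (m, d, d)
    A = 2.0 * (rest - p0[:, None, :])  # (m, d, d)
    b = np.sum(rest**2, axis=2) - np.sum(p0**2, axis=1)[:, None]  # (m, d)
    radii = np.empty(simplices.shape[0])
    for i in range(simplices.shape[0]):
        try:
            center = np.linalg.solve(A[i], b[i])
        except np.linalg.LinAlgError:
            radii[i] = np.inf
            continue
        radii[i] = float(np.linalg.norm(center - p0[i]))
    return radii


def _simplex_measures(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Unsigned simplex measures in nm^d (area or volume)."""
    d = points.shape[1]
    p0 = points[simplices[:, 0]]
    edges = points[simplices[:, 1:]] - p0[:, None, :]
    dets = np.linalg.det(edges)
    factorial = 2.0 if d == 2 else 6.0
    return np.abs(dets) / factorial


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.n_components = 0  # counts only activated members

    def activate(self) -> None:
        self.n_components += 1

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[ri] = rj
            self.n_components -= 1


def _critical_alpha(
    simplices: np.ndarray, radii: np.ndarray, n_points: int
) -> float:
    """Smallest spectrum value giving an all-points, simply connected shape.

    Simplices are admitted in order of increasing circumradius while a
    union-find over facet adjacency tracks the number of regions, a counter
    tracks how many input points are vertices of an admitted simplex, and
    incremental face counts track the Euler characteristic of the retained
    complex.  The critical alpha is the first circumradius at which every
    point is covered, the complex forms a single facet-connected region and
    its Euler characteristic is 1 — i.e. the shape envelops all points
    without the spurious interior holes that point coverage alone allows on
    uniformly sampled clusters (in 2D the three conditions are exactly
    simple connectivity; in 3D, Euler characteristic 1 is the practical
    proxy for the absence of tunnels and voids).
    """
    from itertools import combinations

    order = np.argsort(radii, kind="stable")
    uf = _UnionFind(len(order))
    facet_owner: dict[tuple, int] = {}
    covered = np.zeros(n_points, dtype=bool)
    n_covered = 0
    m, v = simplices.shape
    seen_faces: set[tuple] = set()
    euler = 0
    sign = {dim: (-1) ** (dim - 1) for dim in range(1, v + 1)}
    idx = 0
    while idx < m:
        # admit all simplices sharing the current circumradius together
        alpha = radii[order[idx]]
        if not np.isfinite(alpha):
            break
        while idx < m and radii[order[idx]] == alpha:
            s = order[idx]
            uf.activate()
            verts = sorted(int(p) for p in simplices[s])
            for p in verts:
                if not covered[p]:
                    covered[p] = True
                    n_covered += 1
            for size in range(1, v + 1):
                for face in combinations(verts, size):
                    if face not in seen_faces:
                        seen_faces.add(face)
                        euler += sign[size]
            for drop in range(v):
                facet = tuple(verts[:drop] + verts[drop + 1 :])
                other = facet_owner.setdefault(facet, int(s))
                if other != s:
                    uf.union(int(s), other)
            idx += 1
        if n_covered == n_points and uf.n_components == 1 and euler == 1:
            return float(alpha)
    return float("inf")


def _boundary_facets(simplices: np.ndarray) -> np.ndarray:
    """Facets appearing in exactly one retained simplex."""
    if simplices.size == 0:
        return np.empty((0, max(simplices.shape[1] - 1, 0)), dtype=int)
    m, v = simplices.shape
    facets = []
    for drop in range(v):
        keep = [j for j in range(v) if j != drop]
        facets.append(np.sort(simplices[:, keep], axis=1))
    allf = np.concatenate(facets, axis=0)
    uniq, counts = np.unique(allf, axis=0, return_counts=True)
    return uniq[counts == 1]


def alpha_shape(points: np.ndarray, alpha: float | str = "auto") -> AlphaShapeHull:
    """Concave hull of a point set by circumradius-filtered Delaunay simplices.

    Parameters
    ----------
    points
        (n, d) coordinates in nm, d in {2, 3}; needs at least d + 1 affinely
        independent points.
    alpha
        Circumradius threshold in nm, ``np.inf`` for the convex hull, or
        ``"auto"`` for the critical alpha (smallest value whose shape uses
        every input point and forms a single region).

    Raises
    ------
    GeometryError
        For degenerate (collinear/coplanar or too small) point sets; callers
        that tolerate degeneracy should catch it and record measure 0 with a
        flag.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] not in (2, 3):
        raise InputError("points must be (n, 2) or (n, 3)")
    d = points.shape[1]
    if points.shape[0] < d + 1:
        raise GeometryError(
            f"need at least {d + 1} points to triangulate, got {points.shape[0]}"
        )
    try:
        tri = Delaunay(points)
    except QhullError as exc:
        raise GeometryError(f"degenerate point set: {exc}") from exc
    simplices = tri.simplices
    radii = _simplex_circumradii(points, simplices)
    if alpha == "auto":
        alpha_val = _critical_alpha(simplices, radii, points.shape[0])
    else:
        alpha_val = float(alpha)
        if not alpha_val > 0:
            raise InputError("alpha must be positive")
    retain = radii <= alpha_val
    kept = simplices[retain]
    measures_nm = _simplex_measures(points, kept)
    scale = NM2_PER_UM2 if d == 2 else NM3_PER_UM3
    return AlphaShapeHull(
        points=points,
        simplices=kept,
        alpha=alpha_val,
        measure=float(measures_nm.sum()) / scale,
        boundary=_boundary_facets(kept),
        circumradii=radii[retain],
    )


def _equivalent_diameter(measure_um: float, d: int) -> float:
    """Diameter (nm) of the disk/sphere with the given measure."""
    if measure_um <= 0:
        return 0.0
    if d == 2:
        area_nm = measure_um * NM2_PER_UM2
        return 2.0 * np.sqrt(area_nm / np.pi)
    vol_nm = measure_um * NM3_PER_UM3
    return 2.0 * (3.0 * vol_nm / (4.0 * np.pi)) ** (1.0 / 3.0)


def cluster_stats(
    points: np.ndarray,
    labeling: ClusterLabeling,
    alpha: float | str = "auto",
    channel: str = "ch1",
) -> tuple[pd.DataFrame, dict]:
    """Per-cluster geometry statistics and image-level medians.

    One row per non-noise cluster with localization count, hull measure
    (µm^d), density (count / measure), equivalent diameter (nm) and centroid.
    Clusters too small or too degenerate to triangulate are reported with
    their count only (``valid_geometry = False``) and excluded from the
    medians.  The summary dict carries the median count, measure and density
    over geometrically valid clusters.
    """
    points = np.asarray(points, dtype=float)
    labels = labeling.labels
    if len(labels) != points.shape[0]:
        raise InputError("labeling length does not match points")
    d = points.shape[1]
    rows = []
    for c in range(labeling.k):
        cl = points[labels == c]
        row: dict = {"cluster": c, "channel": channel, "n": int(cl.shape[0])}
        centroid = cl.mean(axis=0)
        for ax, val in zip("xyz", centroid):
            row[f"centroid_{ax}"] = float(val)
        try:
            hull = alpha_shape(cl, alpha)
            row["measure"] = hull.measure
            row["density"] = cl.shape[0] / hull.measure if hull.measure > 0 else np.nan
            row["equivalent_diameter"] = _equivalent_diameter(hull.measure, d)
            row["alpha"] = hull.alpha
            row["valid_geometry"] = hull.measure > 0
        except GeometryError:
            row.update(
                measure=0.0,
                density=np.nan,
                equivalent_diameter=0.0,
                alpha=np.nan,
                valid_geometry=False,
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    valid = df[df["valid_geometry"]] if len(df) else df
    summary = {
        "channel": channel,
        "n_clusters": int(labeling.k),
        "n_valid": int(len(valid)),
        "median_n": float(valid["n"].median()) if len(valid) else np.nan,
        "median_measure": float(valid["measure"].median()) if len(valid) else np.nan,
        "median_density": float(valid["density"].median()) if len(valid) else np.nan,
    }
    return df, summary


def _centroids(points: np.ndarray, labeling: ClusterLabeling) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    d = points.shape[1] if points.ndim == 2 and points.shape[1] else 2
    if labeling.k == 0:
        return np.zeros((0, d))
    return np.array(
        [points[labeling.labels == c].mean(axis=0) for c in range(labeling.k)]
    )


def corona_composition(
    points_ch1: np.ndarray,
    labeling_ch1: ClusterLabeling,
    points_ch2: np.ndarray,
    labeling_ch2: ClusterLabeling,
    match_radius: float = 250.0,
    purity: float = 0.9,
) -> pd.DataFrame:
    """Merge per-channel clusters into corona objects and classify them.

    Cross-channel cluster pairs with centroids within ``match_radius`` nm are
    merged (greedy, by ascending centroid distance, each cluster used once).
    Each object's channel-1 fraction ``f = n1 / (n1 + n2)`` classifies it:
    ``initial`` when f >= purity, ``exchanged`` when f <= 1 − purity, else
    ``mixed``; ties at the purity boundary fall to the pure class.  Unmatched
    clusters become single-channel objects classed by their own channel.
    """
    if not (0.5 < purity <= 1.0):
        raise InputError("purity must lie in (0.5, 1]")
    if not match_radius > 0:
        raise InputError("match_radius must be > 0")
    c1 = _centroids(np.asarray(points_ch1, dtype=float), labeling_ch1)
    c2 = _centroids(np.asarray(points_ch2, dtype=float), labeling_ch2)
    n1_counts = np.bincount(
        labeling_ch1.labels[labeling_ch1.labels != NOISE], minlength=labeling_ch1.k
    )
    n2_counts = np.bincount(
        labeling_ch2.labels[labeling_ch2.labels != NOISE], minlength=labeling_ch2.k
    )

    pairs: list[tuple[float, int, int]] = []
    if len(c1) and len(c2):
        tree = cKDTree(c2)
        for i, cen in enumerate(c1):
            for j in tree.query_ball_point(cen, r=match_radius):
                pairs.append((float(np.linalg.norm(cen - c2[j])), i, int(j)))
    pairs.sort()
    used1: set[int] = set()
    used2: set[int] = set()
    rows = []

    def classify(f: float) -> str:
        if f >= purity:
            return "initial"
        if f <= 1.0 - purity:
            return "exchanged"
        return "mixed"

    for dist, i, j in pairs:
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        n1, n2 = int(n1_counts[i]), int(n2_counts[j])
        f = n1 / (n1 + n2)
        centroid = (n1 * c1[i] + n2 * c2[j]) / (n1 + n2)
        rows.append(
            {
                "cluster_ch1": i,
                "cluster_ch2": j,
                "n_ch1": n1,
                "n_ch2": n2,
                "fraction_ch1": f,
                "class": classify(f),
                "centroid_distance": dist,
                **{f"centroid_{ax}": float(v) for ax, v in zip("xyz", centroid)},
            }
        )
    for i in range(labeling_ch1.k):
        if i not in used1:
            rows.append(
                {
                    "cluster_ch1": i,
                    "cluster_ch2": -1,
                    "n_ch1": int(n1_counts[i]),
                    "n_ch2": 0,
                    "fraction_ch1": 1.0,
                    "class": "initial",
                    "centroid_distance": np.nan,
                    **{f"centroid_{ax}": float(v) for ax, v in zip("xyz", c1[i])},
                }
            )
    for j in range(labeling_ch2.k):
        if j not in used2:
            rows.append(
                {
                    "cluster_ch1": -1,
                    "cluster_ch2": j,
                    "n_ch1": 0,
                    "n_ch2": int(n2_counts[j]),
                    "fraction_ch1": 0.0,
                    "class": "exchanged",
                    "centroid_distance": np.nan,
                    **{f"centroid_{ax}": float(v) for ax, v in zip("xyz", c2[j])},
                }
            )
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["cluster_ch1", "cluster_ch2"]).reset_index(drop=True)
        df.insert(0, "object", np.arange(len(df)))
    return df


@dataclass
class RadialProfile:
    """Radial density profile of a corona object around its channel-1 core."""

    bin_edges: np.ndarray
    density: dict[str, np.ndarray]  # per-channel counts / shell measure (µm^−d)
    counts: dict[str, np.ndarray]
    core_diameter: float | None  # 2 × 90th-percentile channel-1 radius, nm
    reference_channel: str
    valid: bool


def radial_profile(
    points_by_channel: Mapping[str, np.ndarray],
    n_bins: int = 20,
    reference_channel: str = "ch1",
    min_reference_points: int = 10,
) -> RadialProfile:
    """Per-channel radial density around the reference-channel centroid.

    Radii are measured from the centroid of the reference (core) channel;
    each channel's counts per circular annulus / spherical shell are divided
    by the shell measure.  The core-diameter estimate is twice the 90th
    percentile of the reference channel's radii; for points uniform in a
    ball of radius R it converges to ``2 R · 0.9^(1/d)``.

    Objects with fewer than ``min_reference_points`` reference localizations
    are flagged (``valid = False``) and carry no estimate.
    """
    ref = np.asarray(points_by_channel.get(reference_channel, np.empty((0, 2))), float)
    if ref.shape[0] < min_reference_points:
        return RadialProfile(
            bin_edges=np.empty(0),
            density={},
            counts={},
            core_diameter=None,
            reference_channel=reference_channel,
            valid=False,
        )
    d = ref.shape[1]
    center = ref.mean(axis=0)
    radii = {
        ch: np.linalg.norm(np.asarray(pts, float) - center, axis=1)
        for ch, pts in points_by_channel.items()
    }
    r_max = max((r.max() for r in radii.values() if r.size), default=1.0)
    if r_max <= 0:
        r_max = 1.0  # all points coincide with the centroid
    edges = np.linspace(0.0, r_max, n_bins + 1)
    scale = NM2_PER_UM2 if d == 2 else NM3_PER_UM3
    if d == 2:
        shell_measure = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2) / scale
    else:
        shell_measure = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3) / scale
    counts = {}
    density = {}
    for ch, r in radii.items():
        c, _ = np.histogram(r, bins=edges)
        counts[ch] = c
        density[ch] = c / shell_measure
    core = 2.0 * float(np.percentile(radii[reference_channel], 90))
    return RadialProfile(
        bin_edges=edges,
        density=density,
        counts=counts,
        core_diameter=core,
        reference_channel=reference_channel,
        valid=True,
    )
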