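"""Independent brute-force oracles used by the test suite.

Every oracle re-derives its quantity by a route different from the package
implementation: O(n²) all-pairs scans, graph search over an explicit
adjacency matrix, closed-form circumradius formulas (Heron in 2D, the
opposite-edge-product formula in 3D) and a direct cell-means ANOVA fit.
"""

from __future__ import annotations

import numpy as np

NOISE = -1


def brute_force_neighbor_counts(points: np.ndarray, radius: float) -> np.ndarray:
    """All-pairs count of other points within Euclidean distance <= radius."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    counts = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(n):
            if i != j and np.linalg.norm(points[i] - points[j]) <= radius:
                counts[i] += 1
    return counts


def brute_force_dbscan(points: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """DBSCAN by explicit adjacency matrix and DFS over core points.

    Semantics: core iff closed eps-neighborhood >= min_pts; clusters are
    components of core points under mutual eps-reachability; border points
    join the cluster of their smallest-index core neighbor; ids renumbered
    by ascending minimum member index.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    dist = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    adj = dist <= eps
    core = adj.sum(axis=1) >= min_pts  # closed neighborhood includes self
    labels = np.full(n, NOISE, dtype=int)
    comp = 0
    for start in range(n):
        if not core[start] or labels[start] != NOISE:
            continue
        stack = [start]
        labels[start] = comp
        while stack:
            i = stack.pop()
            for j in np.flatnonzero(adj[i] & core):
                if labels[j] == NOISE:
                    labels[j] = comp
                    stack.append(j)
        comp += 1
    for i in range(n):
        if core[i]:
            continue
        core_nb = np.flatnonzero(adj[i] & core)
        if core_nb.size:
            labels[i] = labels[core_nb.min()]
    # renumber by ascending minimum member index
    out = np.full(n, NOISE, dtype=int)
    mapping: dict[int, int] = {}
    for i in range(n):
        if labels[i] == NOISE:
            continue
        if labels[i] not in mapping:
            mapping[labels[i]] = len(mapping)
        out[i] = mapping[labels[i]]
    return out


def core_point_partition(labels: np.ndarray, core_mask: np.ndarray) -> set[frozenset]:
    """Partition of core points implied by a labeling (id-invariant)."""
    parts: dict[int, set[int]] = {}
    for i in np.flatnonzero(core_mask):
        parts.setdefault(labels[i], set()).add(int(i))
    return {frozenset(v) for v in parts.values()}


def variance_ratio_two_pass(points: np.ndarray, labels: np.ndarray) -> float:
    """Independent two-pass evaluation of the between/within variance ratio."""
    mask = labels != NOISE
    pts = np.asarray(points, dtype=float)[mask]
    labs = np.asarray(labels)[mask]
    uniq = np.unique(labs)
    k, n = len(uniq), len(pts)
    if k < 2 or n == 0:
        return float("-inf")
    grand = pts.mean(axis=0)
    B = sum(
        (labs == c).sum() * np.sum((pts[labs == c].mean(axis=0) - grand) ** 2)
        for c in uniq
    )
    W = sum(np.sum((pts[labs == c] - pts[labs == c].mean(axis=0)) ** 2) for c in uniq)
    if W == 0:
        return float("inf") if B > 0 else float("-inf")
    return (B / (k - 1)) / (W / (n - k))


def circumradius_closed_form(vertices: np.ndarray) -> float:
    """Circumradius from vertex coordinates by closed-form edge formulas.

    Triangle: R = abc / (4 A) with A from Heron's formula.  Tetrahedron:
    R = sqrt((aa'+bb'+cc')(aa'+bb'-cc')(aa'-bb'+cc')(-aa'+bb'+cc')) / (24 V)
    with (a, a'), (b, b'), (c, c') the three opposite-edge pairs.
    """
    v = np.asarray(vertices, dtype=float)
    if v.shape[0] == 3:
        a = np.linalg.norm(v[1] - v[2])
        b = np.linalg.norm(v[0] - v[2])
        c = np.linalg.norm(v[0] - v[1])
        s = (a + b + c) / 2
        area_sq = s * (s - a) * (s - b) * (s - c)
        if area_sq <= 0:
            return float("inf")
        return a * b * c / (4.0 * np.sqrt(area_sq))
    assert v.shape[0] == 4
    a = np.linalg.norm(v[0] - v[1]) * np.linalg.norm(v[2] - v[3])
    b = np.linalg.norm(v[0] - v[2]) * np.linalg.norm(v[1] - v[3])
    c = np.linalg.norm(v[0] - v[3]) * np.linalg.norm(v[1] - v[2])
    vol = abs(np.linalg.det(v[1:] - v[0])) / 6.0
    if vol == 0:
        return float("inf")
    prod = (a + b + c) * (a + b - c) * (a - b + c) * (-a + b + c)
    if prod < 0:
        return float("inf")
    return float(np.sqrt(prod) / (24.0 * vol))


def simplex_measure_closed_form(vertices: np.ndarray) -> float:
    """Triangle area by Heron; tetrahedron volume by the Cayley determinant."""
    v = np.asarray(vertices, dtype=float)
    if v.shape[0] == 3:
        a = np.linalg.norm(v[1] - v[2])
        b = np.linalg.norm(v[0] - v[2])
        c = np.linalg.norm(v[0] - v[1])
        s = (a + b + c) / 2
        return float(np.sqrt(max(s * (s - a) * (s - b) * (s - c), 0.0)))
    return float(abs(np.linalg.det(v[1:] - v[0])) / 6.0)


def brute_force_alpha_measure(
    points: np.ndarray, simplices: np.ndarray, alpha: float
) -> float:
    """Sum of closed-form measures of Delaunay simplices with R <= alpha (nm^d)."""
    total = 0.0
    for s in simplices:
        if circumradius_closed_form(points[s]) <= alpha:
            total += simplex_measure_closed_form(points[s])
    return total


def cell_means_anova(values, a_labels, b_labels) -> dict:
    """Balanced two-way ANOVA by direct cell-means fitting.

    Fits the cell-means model, then decomposes by averaging fitted effects:
    SS_A from marginal A means, SS_B from marginal B means, SS_AB from cell
    mean residuals, SS_within from observations around cell means.
    """
    values = np.asarray(values, dtype=float)
    a_labels = np.asarray(a_labels)
    b_labels = np.asarray(b_labels)
    A = np.unique(a_labels)
    B = np.unique(b_labels)
    r = len(values) // (len(A) * len(B))
    grand = values.mean()
    cell = {
        (a, b): values[(a_labels == a) & (b_labels == b)].mean()
        for a in A
        for b in B
    }
    a_mean = {a: values[a_labels == a].mean() for a in A}
    b_mean = {b: values[b_labels == b].mean() for b in B}
    ss_a = r * len(B) * sum((a_mean[a] - grand) ** 2 for a in A)
    ss_b = r * len(A) * sum((b_mean[b] - grand) ** 2 for b in B)
    ss_ab = r * sum(
        (cell[(a, b)] - a_mean[a] - b_mean[b] + grand) ** 2 for a in A for b in B
    )
    ss_within = sum(
        np.sum((values[(a_labels == a) & (b_labels == b)] - cell[(a, b)]) ** 2)
        for a in A
        for b in B
    )
    df_a, df_b = len(A) - 1, len(B) - 1
    df_ab = df_a * df_b
    df_within = len(A) * len(B) * (r - 1)
    ms_within = ss_within / df_within
    return {
        "ss": {"A": ss_a, "B": ss_b, "AB": ss_ab, "within": ss_within},
        "F": {
            "A": (ss_a / df_a) / ms_within,
            "B": (ss_b / df_b) / ms_within,
            "AB": (ss_ab / df_ab) / ms_within,
        },
    }
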