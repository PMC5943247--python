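"""Independent brute-force reference implementations used only by tests.

These are deliberately naive O(n^2)/O(n^3) algorithms built from the
textbook definitions, sharing no code with the package.
"""

import numpy as np


def canonical_partition(labels):
    """Relabel clusters by first appearance so partitions compare equal."""
    labels = np.asarray(labels)
    out = np.full(len(labels), -1, dtype=int)
    seen = {}
    for i, l in enumerate(labels):
        if l == -1:
            continue
        if l not in seen:
            seen[l] = len(seen)
        out[i] = seen[l]
    return out


def brute_force_dbscan(X, eps, min_pts):
    """Textbook density-based clustering from the full distance matrix.

    Core points: >= min_pts neighbours within eps, counting self.
    Clusters: connected components of cores linked within eps. Border
    points take the cluster of their lowest-index core neighbour.
    """
    X = np.asarray(X, float)
    n = len(X)
    if n == 0:
        return np.empty(0, dtype=int)
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    nbr = d <= eps
    core = nbr.sum(1) >= min_pts

    labels = np.full(n, -1, dtype=int)
    cid = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        # flood-fill this core component
        stack = [i]
        labels[i] = cid
        while stack:
            j = stack.pop()
            for k in np.flatnonzero(nbr[j] & core):
                if labels[k] == -1:
                    labels[k] = cid
                    stack.append(k)
        cid += 1
    for i in range(n):
        if labels[i] == -1 and not core[i]:
            cores_near = np.flatnonzero(nbr[i] & core)
            if len(cores_near):
                labels[i] = labels[cores_near[0]]
    return canonical_partition(labels)


def brute_force_centroid_linkage(X, R, min_count=1):
    """Sequential recombination, recomputing the full centroid distance
    matrix from scratch at every step.

    Returns (merge_sequence, labels) in the same conventions as the
    package: initial cluster ids 0..n-1, merged cluster from step k gets
    id n+k, pairs recorded as (min_id, max_id, distance), ties broken by
    the smallest (i, j) id pair.
    """
    X = np.asarray(X, float)
    n = len(X)
    clusters = {i: [i] for i in range(n)}   # id -> member point indices
    next_id = n
    seq = []
    while len(clusters) > 1:
        ids = sorted(clusters)
        cents = np.array([X[clusters[i]].mean(0) for i in ids])
        diff = cents[:, None, :] - cents[None, :, :]
        dm = np.sqrt((diff**2).sum(-1))
        iu = np.triu_indices(len(ids), k=1)
        d = dm[iu].min()
        if d > R:
            break
        tie_mask = dm[iu] == d
        ties = [(ids[a], ids[b]) for a, b in
                zip(iu[0][tie_mask], iu[1][tie_mask])]
        i, j = min(ties)
        seq.append((i, j, float(d)))
        clusters[next_id] = clusters.pop(i) + clusters.pop(j)
        next_id += 1
    labels = np.full(n, -1, dtype=int)
    for cid in sorted(clusters):
        mem = clusters[cid]
        if len(mem) >= min_count:
            labels[mem] = cid
    return seq, canonical_partition(labels)


def point_in_polygon(px, py, vertices):
    """Ray casting: count crossings of a rightward horizontal ray."""
    inside = False
    verts = list(vertices)
    n = len(verts)
    for k in range(n):
        x1, y1 = verts[k]
        x2, y2 = verts[(k + 1) % n]
        if (y1 > py) != (y2 > py):
            x_cross = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_cross:
                inside = not inside
    return inside


def convex_hull_area_shoelace(points):
    """Gift-wrapping hull followed by the shoelace formula."""
    pts = np.asarray(points, float)
    pts = np.unique(pts, axis=0)
    if len(pts) < 3:
        return 0.0
    # gift wrapping (Jarvis march)
    start = np.lexsort((pts[:, 1], pts[:, 0]))[0]
    hull = [start]
    while True:
        p = hull[-1]
        q = (p + 1) % len(pts)
        for r in range(len(pts)):
            u, v = pts[q] - pts[p], pts[r] - pts[p]
            cross = u[0] * v[1] - u[1] * v[0]
            if cross < 0 or (cross == 0 and
                             np.linalg.norm(pts[r] - pts[p]) >
                             np.linalg.norm(pts[q] - pts[p])):
                q = r
        if q == start:
            break
        hull.append(q)
        if len(hull) > len(pts):  # degenerate safeguard
            break
    h = pts[hull]
    x, y = h[:, 0], h[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2)
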