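"""Independent brute-force oracles used by the test suite.

These deliberately re-derive every quantity from first principles —
exhaustive spanning-tree enumeration via Pruefer sequences, LP-based
convex-hull membership, direct formula sums — so the package kernels are
checked against code that shares none of their implementation.
"""

from itertools import product

import numpy as np
from scipy.optimize import linprog


def pruefer_to_edges(seq, n):
    """Decode a Pruefer sequence into the edge list of its labelled tree."""
    degree = [1] * n
    for node in seq:
        degree[node] += 1
    edges = []
    seq = list(seq)
    for node in seq:
        for leaf in range(n):
            if degree[leaf] == 1:
                edges.append((leaf, node))
                degree[leaf] -= 1
                degree[node] -= 1
                break
    u, v = [i for i in range(n) if degree[i] == 1]
    edges.append((u, v))
    return edges


def exhaustive_mst(dist):
    """Minimum spanning tree by enumerating all n^(n-2) labelled trees."""
    n = dist.shape[0]
    best_edges, best_w = None, np.inf
    for seq in product(range(n), repeat=max(n - 2, 0)):
        edges = pruefer_to_edges(seq, n)
        w = sum(dist[i, j] for i, j in edges)
        if w < best_w - 1e-15:
            best_w, best_edges = w, edges
    return best_edges, best_w


def feve_bruteforce(pts, weights):
    """FEve from the exhaustively found MST and the defining formula."""
    from scipy.spatial.distance import pdist, squareform

    dist = squareform(pdist(pts))
    edges, _ = exhaustive_mst(dist)
    S = len(pts)
    ew = np.array([dist[i, j] / (weights[i] + weights[j]) for i, j in edges])
    pew = ew / ew.sum()
    thr = 1.0 / (S - 1)
    return (np.minimum(pew, thr).sum() - thr) / (1.0 - thr)


def fdis_bruteforce(pts, weights):
    centroid = sum(w * p for w, p in zip(weights, pts))
    return sum(
        w * np.sqrt(((p - centroid) ** 2).sum()) for w, p in zip(weights, pts)
    )


def fdiv_bruteforce(pts, weights, vertex_rows):
    G = np.mean([pts[i] for i in vertex_rows], axis=0)
    dG = np.array([np.sqrt(((p - G) ** 2).sum()) for p in pts])
    mean_dG = dG.mean()
    delta_d = sum(w * (d - mean_dG) for w, d in zip(weights, dG))
    delta_abs = sum(w * abs(d - mean_dG) for w, d in zip(weights, dG))
    return (delta_d + mean_dG) / (delta_abs + mean_dG)


def is_hull_vertex_lp(pts, i, tol=1e-9):
    """True iff point i is NOT a convex combination of the other points."""
    others = np.delete(pts, i, axis=0)
    k = len(others)
    # feasibility LP: lambda >= 0, sum lambda = 1, others^T lambda = pts[i]
    A_eq = np.vstack([others.T, np.ones(k)])
    b_eq = np.append(pts[i], 1.0)
    res = linprog(np.zeros(k), A_eq=A_eq, b_eq=b_eq, bounds=[(0, None)] * k)
    return not res.success or np.linalg.norm(A_eq @ res.x - b_eq) > tol


def gower_bruteforce(matrix, kinds):
    """Pairwise Gower by explicit per-pair, per-trait loops."""
    from scipy.stats import rankdata

    cols = list(matrix.columns)
    X = {c: matrix[c].to_numpy(float) for c in cols}
    for c in cols:
        if kinds[c] == "ordinal":
            X[c] = rankdata(X[c])
    n = len(matrix)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            tot = 0.0
            for c in cols:
                x = X[c]
                if kinds[c] == "binary":
                    tot += 0.0 if x[i] == x[j] else 1.0
                else:
                    rng = x.max() - x.min()
                    tot += 0.0 if rng == 0 else abs(x[i] - x[j]) / rng
            D[i, j] = tot / len(cols)
    return D
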