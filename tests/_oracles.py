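"""Independent oracles used by the test suite.

Everything here is implemented from first principles (quaternion RMSD,
brute-force clash enumeration, exhaustive cluster search, affine-gap DP
score), deliberately sharing no code path with the package.
"""

from __future__ import annotations

import numpy as np


def quaternion_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Minimal RMSD via the quaternion characteristic (key-matrix) method."""
    x = np.asarray(mobile, float)
    y = np.asarray(reference, float)
    x = x - x.mean(axis=0)
    y = y - y.mean(axis=0)
    n = x.shape[0]
    g = (x ** 2).sum() + (y ** 2).sum()
    m = x.T @ y
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam_max = np.linalg.eigvalsh(key)[-1]
    msd = max(g - 2.0 * lam_max, 0.0) / n
    return float(np.sqrt(msd))


def brute_force_clashes(
    coords_a: np.ndarray,
    radii_a: np.ndarray,
    coords_b: np.ndarray,
    radii_b: np.ndarray,
    overlap_threshold: float,
) -> set[tuple[int, int]]:
    """All-pairs clash enumeration with explicit loops."""
    out = set()
    for i in range(coords_a.shape[0]):
        for j in range(coords_b.shape[0]):
            d = float(np.sqrt(np.sum((coords_a[i] - coords_b[j]) ** 2)))
            if d < radii_a[i] + radii_b[j] - overlap_threshold:
                out.add((i, j))
    return out


def exhaustive_diagonal_clusters(
    values: np.ndarray, threshold: float, criterion: str
) -> list[tuple[int, int]]:
    """Cluster scan by exhaustive enumeration of all diagonal squares.

    Enumerates every interval [i, j], records which satisfy the criterion,
    then walks left to right taking from each uncovered start the largest
    satisfying square.
    """
    n = values.shape[0]
    ok = {}
    for i in range(n):
        for j in range(i, n):
            if i == j:
                ok[(i, j)] = True
                continue
            block = values[i:j + 1, i:j + 1]
            off = []
            for a in range(block.shape[0]):
                for b in range(block.shape[0]):
                    if a != b:
                        off.append(block[a, b])
            stat = np.mean(off) if criterion == "mean_offdiag" else np.min(off)
            ok[(i, j)] = bool(stat >= threshold)
    clusters = []
    i = 0
    while i < n:
        best = i
        for j in range(i, n):
            if ok[(i, j)]:
                best = j
        clusters.append((i, best))
        i = best + 1
    return clusters


def affine_global_score(
    a: str, b: str, sub: dict, gap_open: float, gap_extend: float
) -> float:
    """Gotoh global-alignment score, affine gaps costing open + extend*(L-1)."""
    n, m = len(a), len(b)
    neg = -1e18
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in b (a aligned to '-')... gap in y
    Y = np.full((n + 1, m + 1), neg)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[(a[i - 1], b[j - 1])]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend)
    return float(max(M[n, m], X[n, m], Y[n, m]))
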