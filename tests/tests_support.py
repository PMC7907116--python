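"""Shared brute-force oracles and analytic test geometries.

Everything here is deliberately independent of the package's vectorized
implementations: plain loops and a direct sparse solve.
"""

import numpy as np


def brute_force_glcm_counts(levels, mask, Q):
    """Ordered-pair counts over all 8-neighbour offsets, both pixels in
    mask (explicit double loop)."""
    H, W = levels.shape
    counts = np.zeros((Q, Q), dtype=np.int64)
    offsets = [(0, 1), (1, 0), (1, 1), (1, -1),
               (0, -1), (-1, 0), (-1, -1), (-1, 1)]
    for r in range(H):
        for c in range(W):
            if not mask[r, c]:
                continue
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < H and 0 <= cc < W and mask[rr, cc]:
                    counts[levels[r, c], levels[rr, cc]] += 1
    return counts


def brute_force_cooccurrence(levels, mask, zeta, eta, Q):
    """Joint and endpoint-multiset marginal over cliques of one offset."""
    H, W = levels.shape
    joint = np.zeros((Q, Q))
    endpoints = []
    for y in range(H):
        for x in range(W):
            xx, yy = x + zeta, y + eta
            if 0 <= xx < W and 0 <= yy < H and mask[y, x] and mask[yy, xx]:
                joint[levels[y, x], levels[yy, xx]] += 1
                endpoints.extend([levels[y, x], levels[yy, xx]])
    n = joint.sum()
    if n == 0:
        return None, None
    marg = np.bincount(endpoints, minlength=Q) / (2 * n)
    return joint / n, marg


def flat_slab_domain(H=20, W=30, top=5, d=10):
    mask = np.zeros((H, W), bool)
    mask[top:top + d + 1, :] = True
    up = np.zeros((H, W), bool)
    up[top, :] = True
    lo = np.zeros((H, W), bool)
    lo[top + d, :] = True
    return mask, up, lo


def tilted_slab_domain(d=20.0, angle_deg=30.0, H=110, W=120):
    theta = np.deg2rad(angle_deg)
    v = d / np.cos(theta)
    mask = np.zeros((H, W), bool)
    up = np.zeros((H, W), bool)
    lo = np.zeros((H, W), bool)
    for c in range(W):
        r0 = 5 + np.tan(theta) * c
        r1 = r0 + v
        if r1 >= H - 1:
            continue
        mask[int(round(r0)):int(round(r1)) + 1, c] = True
        up[int(round(r0)), c] = True
        lo[int(round(r1)), c] = True
    return mask, up, lo


def annulus_domain(r1=12.0, r2=24.0, size=64):
    rr, cc = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    ctr = (size - 1) / 2.0
    rad = np.hypot(rr - ctr, cc - ctr)
    mask = (rad >= r1 - 0.5) & (rad <= r2 + 0.5)
    up = (rad >= r1 - 0.5) & (rad < r1 + 0.5)
    lo = (rad > r2 - 0.5) & (rad <= r2 + 0.5)
    return mask, up, lo


def sparse_laplace_solution(interior, up, lo):
    """Direct sparse solve of the discrete Laplacian with the same
    reflecting closure as the Jacobi iteration; returns interior values."""
    from scipy.sparse import lil_matrix
    from scipy.sparse.linalg import spsolve

    H, W = interior.shape
    domain = interior | up | lo
    idx = -np.ones((H, W), dtype=int)
    ids = np.flatnonzero(interior.ravel())
    idx.ravel()[ids] = np.arange(ids.size)
    A = lil_matrix((ids.size, ids.size))
    b = np.zeros(ids.size)
    for n, flat in enumerate(ids):
        r, c = divmod(flat, W)
        A[n, n] = 4.0
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if not (0 <= rr < H and 0 <= cc < W) or not domain[rr, cc]:
                A[n, n] -= 1.0
            elif interior[rr, cc]:
                A[n, idx[rr, cc]] = -1.0
            elif lo[rr, cc]:
                b[n] += 1.0
    return spsolve(A.tocsr(), b)
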