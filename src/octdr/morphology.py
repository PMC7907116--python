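"""Morphological markers: Laplace-equation layer thickness and Menger
curvature tortuosity.

Thickness
---------
A harmonic potential gamma is solved between the two boundaries of a layer
(Dirichlet conditions: 1 on the lower/outer boundary, 0 on the upper/inner
one) by Jacobi iteration of the second-order central-difference stencil

    gamma_{i+1}(x, y) = 1/4 [gamma_i(x+1,y) + gamma_i(x-1,y)
                             + gamma_i(x,y+1) + gamma_i(x,y-1)].

Streamlines of -grad(gamma), seeded at constant arc-length spacing on the
high-potential boundary, establish point correspondences between the two
boundaries; the thickness sample is the Euclidean distance between the pair
endpoints.  This is insensitive to boundary tilt (it measures normal
separation, not the vertical chord).

Tortuosity
----------
Local boundary tortuosity is |kappa| with kappa = 1/r, the inverse radius of
the circle through three boundary samples (Menger curvature).  The layer's
tortuosity marker concatenates the binned curvature profiles of its upper
and lower boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .descriptors import MarkerProfile


# --------------------------------------------------------------------------
# Laplace field
# --------------------------------------------------------------------------

@dataclass
class HarmonicField:
    """Converged harmonic potential on a layer's pixel grid.

    ``gamma`` is NaN outside mask+boundaries; boundary pixels hold their
    Dirichlet values (upper -> 0, lower -> 1).
    """

    gamma: np.ndarray
    mask: np.ndarray            # interior (updated) pixels
    upper_mask: np.ndarray      # gamma = 0 pixels
    lower_mask: np.ndarray      # gamma = 1 pixels
    iterations: int
    residual: float
    tol: float


@dataclass
class CorrespondencePair:
    start: tuple[float, float]  # (row, col) on the high-potential boundary
    end: tuple[float, float]    # (row, col) on the low-potential boundary
    thickness: float
    path: np.ndarray | None = None


def solve_laplace(
    mask: np.ndarray,
    upper_mask: np.ndarray,
    lower_mask: np.ndarray,
    tol: float = 1e-5,
    max_iter: int | None = None,
) -> HarmonicField:
    """Solve the discrete Laplace equation on ``mask`` by Jacobi iteration.

    Parameters
    ----------
    mask
        Interior pixels to solve for (excluding the boundary pixels).
    upper_mask, lower_mask
        Dirichlet boundary pixels fixed at 0 and 1 respectively.
    tol
        Stop when the max absolute update falls to ``tol`` or below.
    max_iter
        Sweep cap; default ``10 * height**2`` of the mask bounding box.

    Holes (non-mask pixels surrounded by mask) act as obstacles: they are
    never updated and their (zero-gradient) values do not feed the stencil —
    neighbours outside the domain are replaced by the centre value, i.e. a
    reflecting condition.
    """
    mask = np.asarray(mask, dtype=bool)
    upper_mask = np.asarray(upper_mask, dtype=bool)
    lower_mask = np.asarray(lower_mask, dtype=bool)
    interior = mask & ~upper_mask & ~lower_mask
    if not interior.any() and not (upper_mask.any() and lower_mask.any()):
        raise ValueError("empty layer domain")

    rows = np.flatnonzero((interior | upper_mask | lower_mask).any(axis=1))
    height = rows[-1] - rows[0] + 1
    if max_iter is None:
        max_iter = max(200, 10 * int(height) ** 2)

    domain = interior | upper_mask | lower_mask
    gamma = np.zeros(mask.shape, dtype=float)
    gamma[lower_mask] = 1.0
    # initialize interior at 0.5 to halve the transient
    gamma[interior] = 0.5

    def shifted(arr, dr, dc, fill):
        out = np.full_like(arr, np.nan)
        H, W = arr.shape
        r0 = max(0, dr); r1 = min(H, H + dr)
        c0 = max(0, dc); c1 = min(W, W + dc)
        out[r0:r1, c0:c1] = arr[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
        return out

    dom = domain.astype(float)
    residual = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        up = shifted(gamma, -1, 0, np.nan)
        dn = shifted(gamma, 1, 0, np.nan)
        lf = shifted(gamma, 0, -1, np.nan)
        rt = shifted(gamma, 0, 1, np.nan)
        up_d = shifted(dom, -1, 0, 0); dn_d = shifted(dom, 1, 0, 0)
        lf_d = shifted(dom, 0, -1, 0); rt_d = shifted(dom, 0, 1, 0)
        # reflecting closure: out-of-domain neighbours contribute the centre
        num = (np.where(np.nan_to_num(up_d) > 0, up, gamma)
               + np.where(np.nan_to_num(dn_d) > 0, dn, gamma)
               + np.where(np.nan_to_num(lf_d) > 0, lf, gamma)
               + np.where(np.nan_to_num(rt_d) > 0, rt, gamma))
        new = num / 4.0
        delta = np.abs(new - gamma)[interior]
        residual = float(delta.max()) if delta.size else 0.0
        gamma[interior] = new[interior]
        if residual <= tol:
            break
    else:
        raise RuntimeError(
            f"Jacobi iteration did not converge: residual {residual:.3e} "
            f"after {max_iter} sweeps (tol {tol:.1e})"
        )
    from scipy import ndimage
    holes = ndimage.binary_fill_holes(domain) & ~domain
    if holes.any():
        warnings.warn("layer mask has interior holes; treated as obstacles",
                      stacklevel=2)
    out = np.where(domain, gamma, np.nan)
    return HarmonicField(gamma=out, mask=interior, upper_mask=upper_mask,
                         lower_mask=lower_mask, iterations=it,
                         residual=residual, tol=tol)


def _order_boundary_points(bmask: np.ndarray) -> np.ndarray:
    """Order boundary pixels into a polyline of (row, col) floats.

    Layer boundaries are single-valued in the column index, so column order
    suffices; closed curves (e.g. a circular boundary in test geometries)
    are detected by multi-pixel columns and ordered by angle around the
    centroid instead.
    """
    rows, cols = np.nonzero(bmask)
    uniq_cols, inv, counts = np.unique(cols, return_inverse=True,
                                       return_counts=True)
    if counts.max() <= 2:
        mean_rows = np.bincount(inv, weights=rows) / np.bincount(inv)
        return np.column_stack([mean_rows, uniq_cols.astype(float)])
    cr, ccen = rows.mean(), cols.mean()
    ang = np.arctan2(rows - cr, cols - ccen)
    order = np.argsort(ang)
    return np.column_stack([rows[order], cols[order]]).astype(float)


def trace_thickness(
    field: HarmonicField,
    n_seeds: int = 50,
    step: float = 0.5,
    seeds: np.ndarray | None = None,
    keep_paths: bool = False,
) -> list[CorrespondencePair]:
    """Trace streamlines of -grad(gamma) from the high-potential boundary.

    ``n_seeds`` start points are placed at equal arc-length spacing along
    the lower (gamma = 1) boundary polyline (or pass explicit ``seeds`` as
    (row, col) pairs).  Each streamline follows the normalized negative
    gradient with midpoint (RK2) steps of ``step`` pixels, bilinearly
    interpolating the gradient, until the potential crosses 0; the final
    sub-step is linearly interpolated to the exact crossing.  The thickness
    sample is the Euclidean distance between the endpoints.
    """
    gamma = field.gamma
    domain = np.isfinite(gamma)
    g = np.where(domain, gamma, np.nan)
    # extend the potential past the boundaries by signed linear
    # extrapolation, so the bilinear zero contour passes through the
    # low-boundary pixel centres instead of half a pixel beyond them
    gfill = _fill_signed_extrapolation(g)
    gy, gx = np.gradient(gfill)

    if seeds is None:
        poly = _order_boundary_points(field.lower_mask)
        seeds = _resample_polyline(poly, n_seeds)

    H, W = gamma.shape
    max_len = 4.0 * H
    pairs: list[CorrespondencePair] = []
    for r0, c0 in seeds:
        r, c = float(r0), float(c0)
        path = [(r, c)] if keep_paths else None
        traveled = 0.0
        prev = (r, c)
        prev_val = _bilinear(gfill, r, c)
        ok = False
        while traveled < max_len:
            dr1, dc1 = _grad_dir(gy, gx, r, c)
            if dr1 is None:
                break
            rm, cm = r - 0.5 * step * dr1, c - 0.5 * step * dc1
            dr2, dc2 = _grad_dir(gy, gx, rm, cm)
            if dr2 is None:
                dr2, dc2 = dr1, dc1
            rn, cn = r - step * dr2, c - step * dc2
            if not (0 <= rn < H - 1 and 0 <= cn < W - 1):
                rn = min(max(rn, 0.0), H - 1.0)
                cn = min(max(cn, 0.0), W - 1.0)
            val = _bilinear(gfill, rn, cn)
            traveled += step
            if val <= 0.0:
                # interpolate the zero crossing along the last segment
                t = prev_val / (prev_val - val) if prev_val != val else 1.0
                rn = prev[0] + t * (rn - prev[0])
                cn = prev[1] + t * (cn - prev[1])
                r, c = rn, cn
                ok = True
                if keep_paths:
                    path.append((r, c))
                break
            prev = (rn, cn)
            prev_val = val
            r, c = rn, cn
            if keep_paths:
                path.append((r, c))
            if val < 1e-12:
                ok = True
                break
        if not ok:
            warnings.warn("streamline aborted (length cap or left domain); "
                          "pair skipped", stacklevel=2)
            continue
        thick = float(np.hypot(r - r0, c - c0))
        pairs.append(CorrespondencePair(
            start=(float(r0), float(c0)), end=(r, c), thickness=thick,
            path=np.array(path) if keep_paths else None))
    return pairs


def _fill_nearest(arr: np.ndarray) -> np.ndarray:
    from scipy import ndimage
    nanmask = ~np.isfinite(arr)
    if not nanmask.any():
        return arr
    idx = ndimage.distance_transform_edt(nanmask, return_distances=False,
                                         return_indices=True)
    return arr[tuple(idx)]


def _fill_signed_extrapolation(arr: np.ndarray) -> np.ndarray:
    """Fill NaNs by continuing the potential past the boundaries: pixels
    outside the domain get nearest-value -/+ distance * (median interior
    gradient magnitude), signed away from [0, 1]."""
    from scipy import ndimage
    nanmask = ~np.isfinite(arr)
    if not nanmask.any():
        return arr
    dist, idx = ndimage.distance_transform_edt(nanmask, return_indices=True)
    near = arr[tuple(idx)]
    gy, gx = np.gradient(np.where(nanmask, near, arr))
    mag = np.hypot(gy, gx)[~nanmask]
    gbar = float(np.median(mag[mag > 0])) if np.any(mag > 0) else 0.0
    sign = np.where(near < 0.5, -1.0, 1.0)
    return np.where(nanmask, near + sign * dist * gbar, arr)


def _bilinear(arr: np.ndarray, r: float, c: float) -> float:
    H, W = arr.shape
    r = min(max(r, 0.0), H - 1.0 - 1e-9)
    c = min(max(c, 0.0), W - 1.0 - 1e-9)
    r0, c0 = int(r), int(c)
    fr, fc = r - r0, c - c0
    a = arr[r0, c0] * (1 - fr) * (1 - fc) + arr[r0 + 1, c0] * fr * (1 - fc) \
        + arr[r0, c0 + 1] * (1 - fr) * fc + arr[r0 + 1, c0 + 1] * fr * fc
    return float(a)


def _grad_dir(gy: np.ndarray, gx: np.ndarray, r: float, c: float):
    dr = _bilinear(gy, r, c)
    dc = _bilinear(gx, r, c)
    norm = np.hypot(dr, dc)
    if norm < 1e-12 or not np.isfinite(norm):
        return None, None
    return dr / norm, dc / norm


def _resample_polyline(poly: np.ndarray, n: int) -> np.ndarray:
    """n points at equal arc-length spacing along a polyline."""
    seg = np.hypot(*np.diff(poly, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0:
        return np.repeat(poly[:1], n, axis=0)
    targets = np.linspace(0, s[-1], n)
    out = np.empty((n, 2))
    out[:, 0] = np.interp(targets, s, poly[:, 0])
    out[:, 1] = np.interp(targets, s, poly[:, 1])
    return out


# --------------------------------------------------------------------------
# Menger tortuosity
# --------------------------------------------------------------------------

def menger_curvature(p1, p2, p3) -> float:
    """|kappa| = 1/r of the circle through three points.

    Uses the closed-form circumradius kappa = 4 A / (|a| |b| |c|), which is
    algebraically equivalent to solving the three-circle system; collinear
    triples return 0 exactly.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    a = np.linalg.norm(p2 - p1)
    b = np.linalg.norm(p3 - p2)
    c = np.linalg.norm(p3 - p1)
    cross = (p2[0] - p1[0]) * (p3[1] - p1[1]) - (p2[1] - p1[1]) * (p3[0] - p1[0])
    area2 = abs(cross)  # twice the triangle area
    if area2 == 0.0 or a == 0.0 or b == 0.0 or c == 0.0:
        return 0.0
    return float(2.0 * area2 / (a * b * c))


def menger_tortuosity(polyline: np.ndarray, window: int = 5,
                      smooth: int = 3) -> np.ndarray:
    """Curvature profile |kappa| along a boundary polyline.

    For each interior sample p the circle through (p-window, p, p+window)
    gives kappa; a light moving average (width ``smooth``) suppresses the
    staircase curvature of rasterized boundaries before sampling.  Profile
    length is len(polyline) - 2*window.
    """
    poly = np.asarray(polyline, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 3:
        raise ValueError("polyline needs at least 3 points")
    n = poly.shape[0]
    if 2 * window >= n:
        raise ValueError(f"window {window} too large for polyline of {n} points")
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        sm = np.copy(poly)
        for d in range(2):
            sm[:, d] = np.convolve(
                np.pad(poly[:, d], smooth // 2, mode="edge"), kernel,
                mode="valid")[:n]
        poly = sm
    out = np.empty(n - 2 * window)
    for i in range(window, n - window):
        out[i - window] = menger_curvature(poly[i - window], poly[i],
                                           poly[i + window])
    return out


def bin_profile(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Average a 1-D sample sequence into ``n_bins`` contiguous bins
    (NaN-aware; empty bins yield NaN)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return np.full(n_bins, np.nan)
    edges = np.linspace(0, values.size, n_bins + 1).astype(int)
    out = np.full(n_bins, np.nan)
    for b in range(n_bins):
        chunk = values[edges[b]:edges[b + 1]]
        chunk = chunk[np.isfinite(chunk)]
        if chunk.size:
            out[b] = chunk.mean()
    return out


def layer_tortuosity_marker(
    upper_polyline: np.ndarray | None,
    lower_polyline: np.ndarray | None,
    window: int = 5,
    n_bins: int = 10,
    layer: int = 0,
) -> MarkerProfile:
    """Tortuosity marker of a layer: concatenated binned curvature profiles
    of its upper and lower boundaries."""
    profiles = []
    for poly in (upper_polyline, lower_polyline):
        if poly is None:
            warnings.warn("missing boundary; tortuosity marker built from "
                          "the remaining one", stacklevel=2)
            continue
        kappa = menger_tortuosity(np.asarray(poly), window=window)
        profiles.append(bin_profile(kappa, n_bins))
    if not profiles:
        raise ValueError("both boundaries missing")
    return MarkerProfile(values=np.concatenate(profiles), layer=layer,
                         marker="tortuosity")


# --------------------------------------------------------------------------
# Layer-map helpers
# --------------------------------------------------------------------------

def layer_boundary_masks(labels: np.ndarray, layer: int
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interior/upper/lower pixel masks of one layer of a label map.

    The upper (lower) boundary is the topmost (bottommost) in-layer pixel of
    each occupied column.
    """
    lm = np.asarray(labels) == layer
    H, W = lm.shape
    upper = np.zeros_like(lm)
    lower = np.zeros_like(lm)
    cols = np.flatnonzero(lm.any(axis=0))
    for c in cols:
        rows = np.flatnonzero(lm[:, c])
        upper[rows[0], c] = True
        lower[rows[-1], c] = True
    interior = lm & ~upper & ~lower
    return interior, upper, lower


def layer_boundary_polylines(labels: np.ndarray, layer: int
                             ) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Upper and lower boundary polylines of a layer at 1-px column spacing,
    as (row, col) arrays; None when the layer is absent."""
    lm = np.asarray(labels) == layer
    cols = np.flatnonzero(lm.any(axis=0))
    if cols.size == 0:
        return None, None
    up, lo = [], []
    for c in cols:
        rows = np.flatnonzero(lm[:, c])
        up.append((rows[0], c))
        lo.append((rows[-1], c))
    return np.asarray(up, dtype=float), np.asarray(lo, dtype=float)


def layer_thickness_profile(
    labels: np.ndarray,
    layer: int,
    n_bins: int = 10,
    n_seeds: int = 60,
    tol: float = 1e-5,
) -> MarkerProfile:
    """Laplace-streamline thickness marker of one layer, binned by the
    streamline start column for CDF summarization.

    Layers thinner than 3 px in every column (no interior between the two
    boundary pixel rows) fall back to the vertical boundary distance, which
    equals the streamline answer for such bands.
    """
    labels = np.asarray(labels)
    lm = labels == layer
    cols = np.flatnonzero(lm.any(axis=0))
    if cols.size == 0:
        raise ValueError(f"layer {layer} absent from label map")
    interior, upper, lower = layer_boundary_masks(labels, layer)
    col_thick = lm.sum(axis=0)[cols].astype(float)
    if not interior.any():
        # 1-2 px band: thickness is the pixel count per column
        return MarkerProfile(values=bin_profile(col_thick, n_bins),
                             layer=layer, marker="thickness")
    # solve on the layer bounding box only (Jacobi cost scales with area)
    rows = np.flatnonzero(lm.any(axis=1))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    field = solve_laplace(lm[r0:r1, c0:c1], upper[r0:r1, c0:c1],
                          lower[r0:r1, c0:c1], tol=tol)
    pairs = trace_thickness(field, n_seeds=n_seeds)
    if not pairs:
        return MarkerProfile(values=bin_profile(col_thick, n_bins),
                             layer=layer, marker="thickness")
    start_cols = np.array([p.start[1] for p in pairs])
    thicknesses = np.array([p.thickness for p in pairs])
    order = np.argsort(start_cols)
    return MarkerProfile(values=bin_profile(thicknesses[order], n_bins),
                         layer=layer, marker="thickness")
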