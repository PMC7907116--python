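"""Joint-probability segmentation of the twelve retinal layers.

A B-scan is labeled by maximizing the joint model

    P(g, l) = P(g | l) * P_s(l) * P_V(l)

where P(g|l) is an adaptive per-label intensity model (Gaussian mixtures
fitted by EM), P_s(l) an adaptive pixel-wise shape prior built from an
atlas of segmented scans, and P_V(l) a second-order Markov-Gibbs smoothness
term on the 8-neighbour system with analytic Potts potentials (+gamma for
equal neighbour labels, -gamma otherwise, gamma estimated from the atlas
equal-pair frequency).

Pipeline per scan: (1) detect the retina outline (vitreous and choroid
boundaries) with a coarse-to-fine gradient tracker on a Gaussian pyramid;
(2) align the scan to the atlas grid with a thin-plate-spline warp anchored
at landmarks sampled along the two outline curves; (3) fit the intensity
model, initialize each pixel at argmax P(g|l) P_s(l), refine by iterated
conditional modes (ICM) over the smoothness term; (4) enforce the layer
topology by extracting one monotone smoothed boundary per adjacent layer
pair column-wise and relabeling; (5) map the labels back through the
inverse warp.  The result always satisfies the LabelMap ordering invariant
and is deterministic for fixed scan + atlas + parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import ThinPlateSplineTransform, pyramid_gaussian, warp

from .io import BScan, LabelMap

N_LABELS = 13  # background + 12 layers


# ==========================================================================
# Retina outline detection
# ==========================================================================

def detect_retina_outline(scan: BScan | np.ndarray,
                          min_contrast: float = 0.08,
                          smooth_width: int = 9
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Detect the vitreous/retina and retina/choroid boundary curves.

    Coarse-to-fine tracking of the strongest dark-to-bright (upper) and
    bright-to-dark (lower) vertical gradient on a Gaussian pyramid, with a
    moving-average smoothing of the traced curves.  Returns two row-vs-
    column arrays (floats), upper strictly above lower everywhere.

    Raises
    ------
    ValueError
        If more than 20% of columns lack an edge of sufficient contrast
        relative to the image intensity range ("outline not found").
    """
    pixels = scan.pixels if isinstance(scan, BScan) else np.asarray(scan)
    img = np.asarray(pixels, dtype=float)
    rng_ = img.max() - img.min()
    if rng_ <= 0:
        raise ValueError("outline not found: constant image")
    img = (img - img.min()) / rng_

    levels = list(pyramid_gaussian(img, downscale=2, max_layer=3,
                                   preserve_range=True, channel_axis=None))
    # drop levels that are too small for tracking
    levels = [lv for lv in levels if min(lv.shape) >= 16]

    def col_gradient(im):
        sm = ndimage.gaussian_filter(im, 1.5)
        return np.gradient(sm, axis=0)

    # coarsest level: first strong dark->bright edge from the top (the
    # vitreous/retina transition) and last strong bright->dark edge from
    # the bottom (retina/choroid); a plain global argmax would lock onto
    # stronger interior layer edges where the inner layers vanish (fovea)
    coarse = levels[-1]
    gy = col_gradient(coarse)
    Hc, Wc = coarse.shape
    upper = np.empty(Wc)
    lower = np.empty(Wc)
    for c in range(Wc):
        col = gy[:, c]
        pos = np.flatnonzero(col >= 0.3 * max(col.max(), 1e-12))
        if pos.size:
            # peak of the first above-threshold run (the edge centre, not
            # the leading tail of its blur)
            run_end = pos[0]
            while run_end + 1 < Hc and col[run_end + 1] >= col[run_end]:
                run_end += 1
            upper[c] = run_end
        else:
            upper[c] = col.argmax()
        neg = np.flatnonzero(-col >= 0.3 * max(-col.min(), 1e-12))
        neg = neg[neg > upper[c]]
        if neg.size:
            run_start = neg[-1]
            while run_start - 1 > upper[c] and col[run_start - 1] <= col[run_start]:
                run_start -= 1
            lower[c] = run_start
        else:
            lower[c] = min(int(upper[c]) + 1, Hc - 1)

    # refine through finer levels within a window around the upsampled curve
    for lv in reversed(levels[:-1]):
        gy = col_gradient(lv)
        H, W = lv.shape
        prevW = upper.size
        x_old = np.arange(prevW, dtype=float)
        x_new = np.arange(W, dtype=float) * (prevW - 1) / max(W - 1, 1)
        upper = np.interp(x_new, x_old, upper) * 2.0  # 2x upsample per level
        lower = np.interp(x_new, x_old, lower) * 2.0
        win = 4
        for curve, pick in ((upper, np.argmax), (lower, np.argmin)):
            for c in range(W):
                r0 = int(max(0, curve[c] - win))
                r1 = int(min(H, curve[c] + win + 1))
                if r1 <= r0:
                    continue
                curve[c] = r0 + pick(gy[r0:r1, c])
        upper = np.minimum(upper, lower - 1)

    gy = col_gradient(img)
    H, W = img.shape
    ui = np.clip(upper.astype(int), 0, H - 1)
    li = np.clip(lower.astype(int), 0, H - 1)
    cols = np.arange(W)

    def near_curve_contrast(ri):
        vals = np.zeros(W)
        for dr in (-2, -1, 0, 1, 2):
            rr = np.clip(ri + dr, 0, H - 1)
            vals = np.maximum(vals, np.abs(gy[rr, cols]))
        return vals

    contrast_ok = (near_curve_contrast(ui) >= min_contrast / 4) \
        & (near_curve_contrast(li) >= min_contrast / 4)
    if np.mean(~contrast_ok) > 0.20:
        raise ValueError(
            f"outline not found: insufficient edge contrast in "
            f"{np.mean(~contrast_ok):.0%} of columns")

    kernel = np.ones(smooth_width) / smooth_width
    pad = smooth_width // 2
    upper = np.convolve(np.pad(upper, pad, mode="edge"), kernel, "valid")[:W]
    lower = np.convolve(np.pad(lower, pad, mode="edge"), kernel, "valid")[:W]
    lower = np.maximum(lower, upper + 1.0)
    return upper, lower


# ==========================================================================
# Shape atlas and alignment
# ==========================================================================

@dataclass
class ShapeAtlas:
    """Atlas of segmented scans on a common grid with a pixel-wise label
    frequency prior and a reference retina outline."""

    images: list[np.ndarray]
    label_maps: list[np.ndarray]
    prior: np.ndarray               # (13, H, W), sums to 1 over labels
    reference_outline: tuple[np.ndarray, np.ndarray]
    shape: tuple[int, int] = (0, 0)

    @classmethod
    def build(cls, images: list[np.ndarray], label_maps: list[np.ndarray]
              ) -> "ShapeAtlas":
        if len(images) < 3:
            raise ValueError("atlas needs at least 3 entries")
        shape = images[0].shape
        for im, lm in zip(images, label_maps):
            if im.shape != shape or lm.shape != shape:
                raise ValueError("atlas entries must share one grid")
        prior = np.zeros((N_LABELS,) + shape)
        for lm in label_maps:
            for l in range(N_LABELS):
                prior[l] += lm == l
        prior /= len(label_maps)
        majority = prior.argmax(axis=0)
        upper, lower = _outline_from_labels(majority)
        return cls(images=[np.asarray(i, float) for i in images],
                   label_maps=[np.asarray(l) for l in label_maps],
                   prior=prior, reference_outline=(upper, lower),
                   shape=shape)

    def weighted_prior(self, weights: np.ndarray) -> np.ndarray:
        """Label-frequency prior re-weighted per atlas entry."""
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
        prior = np.zeros_like(self.prior)
        for wi, lm in zip(w, self.label_maps):
            for l in range(N_LABELS):
                prior[l] += wi * (lm == l)
        return prior


def _outline_from_labels(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    H, W = labels.shape
    nz = labels > 0
    has = nz.any(axis=0)
    first = np.where(has, nz.argmax(axis=0), 0).astype(float)
    last = np.where(has, H - 1 - nz[::-1].argmax(axis=0), H - 1).astype(float)
    # fill retina-free columns from neighbours
    if not has.all() and has.any():
        x = np.arange(W)
        first = np.interp(x, x[has], first[has])
        last = np.interp(x, x[has], last[has])
    return first, last


def _outline_landmarks(upper: np.ndarray, lower: np.ndarray,
                       n_per_curve: int = 12) -> np.ndarray:
    """Landmarks at equal column fractions along both outline curves,
    as (x, y) = (col, row) pairs."""
    W = upper.size
    cols = np.linspace(0.03 * (W - 1), 0.97 * (W - 1), n_per_curve)
    pts = []
    for curve in (upper, lower):
        rows = np.interp(cols, np.arange(W), curve)
        pts.extend(zip(cols, rows))
    return np.asarray(pts)


@dataclass
class AtlasAlignment:
    """Invertible thin-plate-spline warp between scan and atlas grids."""

    to_scan: ThinPlateSplineTransform    # atlas coords -> scan coords
    to_atlas: ThinPlateSplineTransform   # scan coords -> atlas coords
    atlas_shape: tuple[int, int]
    scan_shape: tuple[int, int]
    landmark_residual: float

    def warp_scan_to_atlas(self, pixels: np.ndarray, order: int = 1
                           ) -> np.ndarray:
        return warp(np.asarray(pixels, float), self.to_scan,
                    output_shape=self.atlas_shape, order=order,
                    mode="edge", preserve_range=True)

    def warp_labels_to_scan(self, labels: np.ndarray) -> np.ndarray:
        out = warp(np.asarray(labels, float), self.to_atlas,
                   output_shape=self.scan_shape, order=0, mode="constant",
                   cval=0, preserve_range=True)
        return np.rint(out).astype(np.int16)

    def warp_labels_to_atlas(self, labels: np.ndarray) -> np.ndarray:
        out = warp(np.asarray(labels, float), self.to_scan,
                   output_shape=self.atlas_shape, order=0, mode="constant",
                   cval=0, preserve_range=True)
        return np.rint(out).astype(np.int16)


def align_to_atlas(scan: BScan | np.ndarray,
                   outline: tuple[np.ndarray, np.ndarray],
                   atlas: ShapeAtlas,
                   n_landmarks_per_curve: int = 12
                   ) -> tuple[np.ndarray, AtlasAlignment]:
    """Estimate the thin-plate-spline warp aligning a scan's retina outline
    with the atlas reference outline; return the resampled scan on the
    atlas grid and the invertible transform.

    Landmarks are corresponding points at equal column fractions along the
    upper and lower outline curves (plus the image corners, which pin the
    spline far from the retina).
    """
    pixels = scan.pixels if isinstance(scan, BScan) else np.asarray(scan)
    src_scan = _outline_landmarks(*outline, n_landmarks_per_curve)
    src_ref = _outline_landmarks(*atlas.reference_outline,
                                 n_landmarks_per_curve)
    _check_landmarks(src_scan)
    _check_landmarks(src_ref)

    try:
        to_scan = ThinPlateSplineTransform.from_estimate(src_ref, src_scan)
        to_atlas = ThinPlateSplineTransform.from_estimate(src_scan, src_ref)
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"alignment error: TPS estimation failed: {exc}")
    if not to_scan or not to_atlas:
        raise ValueError("alignment error: TPS estimation failed")
    residual = float(np.sqrt(np.mean(
        np.sum((to_atlas(src_scan) - src_ref) ** 2, axis=1))))
    align = AtlasAlignment(to_scan=to_scan, to_atlas=to_atlas,
                           atlas_shape=atlas.shape, scan_shape=pixels.shape,
                           landmark_residual=residual)
    return align.warp_scan_to_atlas(pixels), align


def _check_landmarks(pts: np.ndarray) -> None:
    if np.unique(np.round(pts, 6), axis=0).shape[0] < pts.shape[0]:
        raise ValueError("alignment error: coincident landmarks")
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[-1] < 1e-6 * max(sv[0], 1.0):
        raise ValueError("alignment error: collinear landmarks")


# ==========================================================================
# Intensity model: per-label 1-D Gaussian mixtures fitted by EM
# ==========================================================================

@dataclass
class GaussianMixture1D:
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    log_likelihoods: list[float] = field(default_factory=list)

    def pdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)[..., None]
        comp = self.weights / np.sqrt(2 * np.pi * self.variances) \
            * np.exp(-0.5 * (x - self.means) ** 2 / self.variances)
        return comp.sum(axis=-1)


def fit_gmm_1d(values: np.ndarray, n_components: int = 2,
               tol: float = 1e-6, max_iter: int = 200,
               var_floor: float = 0.25) -> GaussianMixture1D:
    """EM fit of a 1-D Gaussian mixture with quantile initialization.

    The log-likelihood trajectory is recorded and is non-decreasing (up to
    the variance floor, which guards degenerate zero-variance components on
    noiseless data).
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("no samples to fit")
    k = int(min(n_components, max(1, np.unique(x).size)))
    qs = np.linspace(0, 100, k + 2)[1:-1]
    means = np.percentile(x, qs).astype(float)
    var = max(x.var(), var_floor)
    variances = np.full(k, var)
    weights = np.full(k, 1.0 / k)
    lls: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        comp = weights / np.sqrt(2 * np.pi * variances) \
            * np.exp(-0.5 * (x[:, None] - means) ** 2 / variances)
        total = comp.sum(axis=1) + 1e-300
        ll = float(np.log(total).sum())
        lls.append(ll)
        resp = comp / total[:, None]
        nk = resp.sum(axis=0) + 1e-12
        weights = nk / x.size
        means = (resp * x[:, None]).sum(axis=0) / nk
        variances = np.maximum(
            (resp * (x[:, None] - means) ** 2).sum(axis=0) / nk, var_floor)
        if np.isfinite(prev) and abs(ll - prev) <= tol * (abs(prev) + 1.0):
            break
        prev = ll
    return GaussianMixture1D(weights=weights, means=means,
                             variances=variances, log_likelihoods=lls)


@dataclass
class IntensityModel:
    """Per-label intensity mixtures P(g | l)."""

    mixtures: dict[int, GaussianMixture1D]

    def log_pdf_table(self, pixels: np.ndarray, labels: range | None = None
                      ) -> np.ndarray:
        labels = labels if labels is not None else range(N_LABELS)
        out = np.empty((len(list(labels)),) + pixels.shape)
        for i, l in enumerate(labels):
            out[i] = np.log(self.mixtures[l].pdf(pixels) + 1e-300)
        return out


def fit_intensity_model(pixels: np.ndarray, labels: np.ndarray,
                        n_components: int = 2, tol: float = 1e-6,
                        max_iter: int = 200, erode: bool = False
                        ) -> IntensityModel:
    """Fit the per-label intensity mixtures on a (warped) scan.

    With ``erode``, each label's sample region is vertically eroded by one
    pixel first, so the thin bands are fitted from their central rows only
    (the boundary rows carry interpolation blur and registration error).
    Labels with no support inherit the parameters pooled over all labeled
    pixels (flagged with a warning).
    """
    pixels = np.asarray(pixels, dtype=float)
    labels = np.asarray(labels)
    pooled = None
    mixtures: dict[int, GaussianMixture1D] = {}
    empty: list[int] = []
    for l in range(N_LABELS):
        sel = labels == l
        if erode:
            core = sel & np.roll(sel, 1, axis=0) & np.roll(sel, -1, axis=0)
            if core.sum() >= 5:
                sel = core
        if sel.sum() < 5:
            empty.append(l)
            continue
        mixtures[l] = fit_gmm_1d(pixels[sel], n_components, tol, max_iter)
    if empty:
        warnings.warn(f"labels {empty} empty; inheriting pooled parameters",
                      stacklevel=2)
        pooled = fit_gmm_1d(pixels, n_components, tol, max_iter)
        for l in empty:
            mixtures[l] = pooled
    return IntensityModel(mixtures=mixtures)


# ==========================================================================
# Smoothness model (analytic Potts potentials) and ICM
# ==========================================================================

OFFSETS_8 = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass
class SmoothnessModel:
    """Potts smoothness on the 8-neighbour system: potential +gamma for an
    equal neighbour pair, -gamma otherwise, with gamma = 2 f_eq - 1
    estimated analytically from the atlas equal-pair frequency."""

    gamma: float

    @classmethod
    def from_atlas(cls, atlas: ShapeAtlas) -> "SmoothnessModel":
        eq = 0
        tot = 0
        for lm in atlas.label_maps:
            for dr, dc in OFFSETS_8:
                a, b = _shift_pair(lm, dr, dc)
                eq += int(np.sum(a == b))
                tot += a.size
        f_eq = eq / max(tot, 1)
        return cls(gamma=float(2 * f_eq - 1))


def _shift_pair(arr: np.ndarray, dr: int, dc: int):
    H, W = arr.shape
    r0 = max(0, -dr); r1 = min(H, H - dr)
    c0 = max(0, -dc); c1 = min(W, W - dc)
    return arr[r0:r1, c0:c1], arr[r0 + dr:r1 + dr, c0 + dc:c1 + dc]


def _neighbor_equal_counts(labels: np.ndarray) -> np.ndarray:
    """(13, H, W) array: for each candidate label, the number of equal
    8-neighbours minus unequal ones, boundary-aware."""
    H, W = labels.shape
    eq = np.zeros((N_LABELS, H, W))
    valid = np.zeros((H, W))
    for dr, dc in OFFSETS_8:
        for sdr, sdc in ((dr, dc), (-dr, -dc)):
            nb = np.full((H, W), -1, dtype=labels.dtype)
            r0 = max(0, sdr); r1 = min(H, H + sdr)
            c0 = max(0, sdc); c1 = min(W, W + sdc)
            nb[r0:r1, c0:c1] = labels[r0 - sdr:r1 - sdr, c0 - sdc:c1 - sdc]
            inb = nb >= 0
            valid += inb
            for l in range(N_LABELS):
                eq[l] += (nb == l)
    return 2 * eq - valid[None]


def icm_refine(log_unary: np.ndarray, init_labels: np.ndarray,
               smooth: SmoothnessModel, beta: float = 1.0,
               max_sweeps: int = 50, change_tol: float = 1e-3
               ) -> np.ndarray:
    """Iterated conditional modes over the 8-neighbour Potts term.

    Pixels are visited on a fixed four-colour 2x2 schedule (each colour
    class updated jointly), which makes the sweep vectorizable while every
    update still conditions on the current neighbour labels; the schedule
    is fixed, so the refinement is deterministic.  Stops when fewer than
    ``change_tol`` of pixels change in a sweep, or at ``max_sweeps``.
    """
    labels = np.asarray(init_labels).copy()
    H, W = labels.shape
    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    colors = (rr % 2) * 2 + (cc % 2)
    w = beta * smooth.gamma
    for _ in range(max_sweeps):
        changed = 0
        for color in range(4):
            msk = colors == color
            score = log_unary + w * _neighbor_equal_counts(labels)
            new = score.argmax(axis=0)
            changed += int(np.sum(new[msk] != labels[msk]))
            labels[msk] = new[msk]
        if changed / labels.size < change_tol:
            break
    else:
        warnings.warn(
            f"ICM did not settle within {max_sweeps} sweeps "
            f"({changed} labels still changing); returning best labeling",
            stacklevel=2)
    return labels


def joint_log_score(log_unary: np.ndarray, labels: np.ndarray,
                    smooth: SmoothnessModel, beta: float = 1.0) -> float:
    """log of the (unnormalized) joint model P(g|l) P_s(l) P_V(l) evaluated
    on a labeling: unary log-probabilities plus the Potts pair sum."""
    labels = np.asarray(labels)
    H, W = labels.shape
    idx = (labels, *np.meshgrid(np.arange(H), np.arange(W), indexing="ij"))
    unary = float(log_unary[idx].sum())
    pair = 0.0
    for dr, dc in OFFSETS_8:
        a, b = _shift_pair(labels, dr, dc)
        pair += float(np.sum(np.where(a == b, 1.0, -1.0)))
    return unary + beta * smooth.gamma * pair


# ==========================================================================
# Topology enforcement
# ==========================================================================

def extract_boundaries(labels: np.ndarray,
                       upper: np.ndarray, lower: np.ndarray,
                       smooth_width: int = 7) -> np.ndarray:
    """Column-wise extraction of the 13 layer band edges b_0..b_12.

    For each adjacent layer pair a single separating row per column is
    chosen to minimize the disagreement with the input labels; the curves
    are smoothed across columns, clamped to the retina outline and ordered
    monotonically.  Returns a (13, W) float array with b_0 = upper outline
    and b_12 = lower outline + 1 (band k covers pixel centres in
    [b_{k-1}, b_k)).
    """
    labels = np.asarray(labels)
    H, W = labels.shape
    up = np.clip(np.rint(upper).astype(int), 0, H - 1)
    lo = np.clip(np.rint(lower).astype(int), 0, H - 1)
    lo = np.maximum(lo, up + 1)

    # bounds[k-1] separates labels <= k from labels > k, k = 1..11
    bounds = np.zeros((11, W))
    for c in range(W):
        col = labels[:, c]
        r0, r1 = up[c], lo[c] + 1
        seg = col[r0:r1]
        for k in range(1, 12):
            le = (seg <= k) & (seg > 0)
            gt = seg > k
            # cost(b) = #{gt above b} + #{le at/below b}; prefix sums over b
            cum_gt = np.concatenate([[0], np.cumsum(gt)])
            cum_le = np.concatenate([[0], np.cumsum(le)])
            cost = cum_gt + (cum_le[-1] - cum_le)
            bounds[k - 1, c] = r0 + int(np.argmin(cost))

    if smooth_width > 1:
        kernel = np.ones(smooth_width) / smooth_width
        pad = smooth_width // 2
        for k in range(11):
            bounds[k] = np.convolve(np.pad(bounds[k], pad, mode="edge"),
                                    kernel, "valid")[:W]
    bounds = np.clip(bounds, up[None, :], (lo + 1)[None, :])
    bounds = np.maximum.accumulate(bounds, axis=0)
    return np.vstack([up[None, :].astype(float), bounds,
                      (lo + 1)[None, :].astype(float)])


def labels_from_boundaries(shape: tuple[int, int],
                           full_bounds: np.ndarray) -> np.ndarray:
    """Rasterize 13 ordered band-edge curves into a label map."""
    H, W = shape
    out = np.zeros(shape, dtype=np.int16)
    rgrid = np.arange(H)[:, None] + 0.5
    for k in range(1, 13):
        band = (rgrid >= full_bounds[k - 1][None, :]) \
            & (rgrid < full_bounds[k][None, :])
        out[band] = k
    return out


def enforce_topology(labels: np.ndarray,
                     upper: np.ndarray, lower: np.ndarray,
                     smooth_width: int = 7) -> np.ndarray:
    """Boundary extraction + relabeling; the output always satisfies the
    LabelMap ordering invariant."""
    full = extract_boundaries(labels, upper, lower, smooth_width)
    return labels_from_boundaries(labels.shape, full)


# ==========================================================================
# Full segmentation
# ==========================================================================

@dataclass
class SegmentationParams:
    beta: float = 0.3               # smoothness weight multiplier
    n_components: int = 2           # mixture components per label
    prior_epsilon: float = 1e-3     # shape-prior smoothing
    icm_sweeps: int = 50
    icm_change_tol: float = 1e-3
    top_k_atlas: int | None = None  # K most-similar atlas entries (None=all)
    boundary_smooth: int = 7


def _warped_outline(outline: tuple[np.ndarray, np.ndarray],
                    align: AtlasAlignment, atlas_shape: tuple[int, int]
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Map the native-scan outline curves onto the atlas grid."""
    aH, aW = atlas_shape
    xa = np.arange(aW, dtype=float)
    out = []
    for curve in outline:
        xs = np.arange(curve.size, dtype=float)
        pts = align.to_atlas(np.column_stack([xs, curve]))
        order = np.argsort(pts[:, 0])
        out.append(np.clip(np.interp(xa, pts[order, 0], pts[order, 1]),
                           0, aH - 1))
    upper, lower = out
    return upper, np.maximum(lower, upper + 1)


def _atlas_similarity(warped: np.ndarray, atlas: ShapeAtlas) -> np.ndarray:
    """Normalized cross-correlation of the warped scan with each entry."""
    a = warped - warped.mean()
    na = np.linalg.norm(a) + 1e-12
    sims = []
    for im in atlas.images:
        b = im - im.mean()
        sims.append(float((a * b).sum() / (na * (np.linalg.norm(b) + 1e-12))))
    return np.asarray(sims)


def segment(scan: BScan | np.ndarray, atlas: ShapeAtlas,
            params: SegmentationParams | None = None,
            return_details: bool = False):
    """Segment the twelve retinal layers of a B-scan.

    See the module docstring for the procedure.  Returns the label map on
    the native scan grid (with ``return_details``, also a dict of the
    intermediate warped-grid quantities: log_unary, init, refined,
    smoothness model, alignment).
    """
    params = params or SegmentationParams()
    pixels = scan.pixels if isinstance(scan, BScan) else np.asarray(scan)

    outline = detect_retina_outline(pixels)
    warped, align = align_to_atlas(pixels, outline, atlas)

    # adaptive shape prior: NCC-weighted label frequencies of the K most
    # similar atlas entries
    sims = _atlas_similarity(warped, atlas)
    weights = np.clip(sims, 1e-6, None)
    if params.top_k_atlas is not None:
        keep = np.argsort(weights)[-params.top_k_atlas:]
        mask = np.zeros_like(weights)
        mask[keep] = 1.0
        weights = weights * mask
    prior = atlas.weighted_prior(weights)
    log_prior = np.log(prior + params.prior_epsilon)

    # the scan's own outline expressed on the atlas grid governs the
    # topology step (the atlas reference outline can be a few pixels off
    # after the warp, which would force background pixels into layers)
    ref_up, ref_lo = _warped_outline(outline, align, atlas.shape)

    # intensity model from the prior's modal labeling, then adaptive
    # refits with topology-regularized labelings (eroded sampling keeps
    # the thin bands' estimates clean)
    current = prior.argmax(axis=0)
    log_unary = log_prior
    for _ in range(3):
        model = fit_intensity_model(warped, current, params.n_components,
                                    erode=True)
        log_pg = model.log_pdf_table(warped)
        log_unary = log_pg + log_prior
        current = enforce_topology(log_unary.argmax(axis=0), ref_up, ref_lo,
                                   smooth_width=params.boundary_smooth)
    init = log_unary.argmax(axis=0)

    smooth = SmoothnessModel.from_atlas(atlas)
    refined = icm_refine(log_unary, init, smooth, beta=params.beta,
                         max_sweeps=params.icm_sweeps,
                         change_tol=params.icm_change_tol)

    # topology on the warped grid, where boundaries are near-horizontal
    full = extract_boundaries(refined, ref_up, ref_lo,
                              smooth_width=params.boundary_smooth)

    # map the 13 band-edge curves back through the TPS at sub-pixel
    # precision (rasterizing the warped labels would cost ~1 px on the
    # thin bands), then rasterize on the native grid
    aW = atlas.shape[1]
    sH, sW = pixels.shape
    xs = np.arange(aW, dtype=float)
    native_bounds = np.empty((13, sW))
    xnat = np.arange(sW, dtype=float)
    for k in range(13):
        pts = align.to_scan(np.column_stack([xs, full[k]]))
        order = np.argsort(pts[:, 0])
        native_bounds[k] = np.interp(xnat, pts[order, 0], pts[order, 1])
    native_bounds = np.clip(native_bounds, 0, sH)
    # pin the outer edges to the outline detected on the native scan
    native_bounds[0] = np.maximum(native_bounds[0], 0)
    native_bounds = np.maximum.accumulate(native_bounds, axis=0)
    native = labels_from_boundaries((sH, sW), native_bounds)
    result = LabelMap(labels=native)
    if return_details:
        topo = labels_from_boundaries(atlas.shape, full)
        return result, {
            "log_unary": log_unary, "init": init, "refined": refined,
            "topology": topo, "smooth": smooth, "beta": params.beta,
            "alignment": align, "outline": outline, "warped": warped,
        }
    return result


def dice_per_layer(pred: np.ndarray, truth: np.ndarray,
                   layers: range = range(1, 13)) -> dict[int, float]:
    """Dice overlap per layer; absent-in-both layers score 1.0."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    out = {}
    for l in layers:
        p = pred == l
        t = truth == l
        denom = p.sum() + t.sum()
        out[l] = 1.0 if denom == 0 else float(2.0 * np.sum(p & t) / denom)
    return out
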