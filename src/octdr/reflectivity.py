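"""Relative-reflectivity normalization and the 1st-order reflectivity
marker.

OCT gray levels are not an absolute measure of backscatter (pupil dilation
and other acquisition factors shift them), so every scan is mapped to a
relative scale anchored at two stable references: the vitreous mean maps to
0 and the RPE mean to 1000,

    I_n = (I_in - RV) / (R12 - RV) * 1000,

with RV the mean vitreous intensity and R12 the mean RPE intensity.  The
RPE is used as the bright anchor because it is typically preserved in early
DR.  The transform is exactly invariant to affine changes of the raw
intensities.

The 1st-order marker of a layer is the mean normalized intensity in each of
a fixed number of column bins per side (temporal/nasal), with a central
foveal region excluded because the inner layers vanish there.  The merged
reflectivity feature of a layer concatenates the 9 CDF percentiles of this
marker (scaled by a training-set confidence bound) with the layer's four
max-scaled GLCM statistics: 13 values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .descriptors import CDFDescriptor, MarkerProfile
from .glcm import GLCMFeatures, GLCMMaxScaler

RPE_LABEL = 12
VITREOUS_MARGIN_ROWS = 3
DEFAULT_FOVEA_EXCLUSION = 0.15  # half-width as a fraction of image width
DEFAULT_BINS_PER_SIDE = 10


@dataclass
class NormalizedScan:
    """Scan on the relative-reflectivity scale (vitreous 0, RPE 1000)."""

    values: np.ndarray
    RV: float
    R12: float


def vitreous_mask(labels: np.ndarray,
                  margin: int = VITREOUS_MARGIN_ROWS) -> np.ndarray:
    """Pixels at least ``margin`` rows above the upper retina boundary.

    The margin keeps edge blur at the vitreous/NFL interface out of the
    reference mean.
    """
    labels = np.asarray(labels)
    H, W = labels.shape
    rows = np.arange(H)[:, None]
    nz = labels > 0
    first = np.where(nz.any(axis=0), nz.argmax(axis=0), H)
    return rows < (first[None, :] - margin)


def normalize_scan(pixels: np.ndarray, labels: np.ndarray) -> NormalizedScan:
    """Map a scan to the relative-reflectivity scale.

    Raises
    ------
    ValueError
        If the RPE is absent, no vitreous region exists, or the two
        reference means are degenerate (|R12 - RV| below 1e-6 of the gray
        range).
    """
    pixels = np.asarray(pixels, dtype=float)
    labels = np.asarray(labels)
    rpe = labels == RPE_LABEL
    if not rpe.any():
        raise ValueError("RPE (label 12) absent: cannot normalize")
    vit = vitreous_mask(labels)
    if not vit.any():
        raise ValueError("no vitreous region above the retina")
    RV = float(pixels[vit].mean())
    R12 = float(pixels[rpe].mean())
    grange = max(float(pixels.max() - pixels.min()), 1.0)
    if abs(R12 - RV) < 1e-6 * grange:
        raise ValueError("degenerate reference: vitreous and RPE means equal")
    values = (pixels - RV) / (R12 - RV) * 1000.0
    return NormalizedScan(values=values, RV=RV, R12=R12)


def first_order_reflectivity(
    nscan: NormalizedScan,
    labels: np.ndarray,
    layer: int,
    bins_per_side: int = DEFAULT_BINS_PER_SIDE,
    fovea_exclusion: float = DEFAULT_FOVEA_EXCLUSION,
) -> MarkerProfile:
    """Binned 1st-order reflectivity marker of one layer.

    Columns outside the central exclusion zone (half-width
    ``fovea_exclusion`` x image width around the centre) are split into
    ``bins_per_side`` contiguous groups on each side; the bin value is the
    mean normalized intensity of the layer's pixels in that group.  Empty
    bins yield NaN sentinels.
    """
    labels = np.asarray(labels)
    lm = labels == layer
    H, W = labels.shape
    cx = W / 2.0
    half = fovea_exclusion * W
    sides = (np.arange(int(np.floor(cx - half))),
             np.arange(int(np.ceil(cx + half)), W))
    values = []
    for side_cols in sides:
        if side_cols.size == 0:
            values.extend([np.nan] * bins_per_side)
            continue
        edges = np.linspace(0, side_cols.size, bins_per_side + 1).astype(int)
        for b in range(bins_per_side):
            cols = side_cols[edges[b]:edges[b + 1]]
            if cols.size == 0:
                values.append(np.nan)
                continue
            sel = lm[:, cols]
            if not sel.any():
                values.append(np.nan)
                continue
            values.append(float(nscan.values[:, cols][sel].mean()))
    profile = MarkerProfile(values=np.array(values), layer=layer,
                            marker="reflectivity1")
    if profile.finite_values().size == 0:
        raise ValueError(
            f"layer {layer} absent outside the foveal exclusion zone")
    return profile


class CIScaler:
    """Per-feature scaling by the upper bound of the training-set 95%
    confidence interval of the mean (mean + 1.96 SE).

    The '95% confidence interval for the mean' scaling of the percentile
    features is directional by construction: values land near 1 for typical
    cases, commensurate with the max-scaled GLCM features.  When the
    training values of a feature are all equal the SE is zero and the
    divisor degenerates to plain mean-scaling (warned); a zero mean falls
    back to pass-through.
    """

    def __init__(self) -> None:
        self.divisor_: np.ndarray | None = None

    def fit(self, values: np.ndarray) -> "CIScaler":
        v = np.atleast_2d(np.asarray(values, dtype=float))
        n = np.maximum(np.sum(np.isfinite(v), axis=0), 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(v, axis=0)
            sd = np.nanstd(v, axis=0, ddof=1) if v.shape[0] > 1 else np.zeros(v.shape[1])
        sd = np.nan_to_num(sd)
        se = sd / np.sqrt(n)
        if np.any(se == 0):
            warnings.warn("zero-width confidence interval for some feature; "
                          "falling back to mean-scaling", stacklevel=2)
        divisor = np.abs(mean) + 1.96 * se
        divisor = np.where(divisor == 0, 1.0, divisor)
        self.divisor_ = divisor
        return self

    def transform(self, values: np.ndarray) -> np.ndarray:
        if self.divisor_ is None:
            raise RuntimeError("scaler not fitted")
        return np.asarray(values, dtype=float) / self.divisor_

    def inverse_transform(self, values: np.ndarray) -> np.ndarray:
        if self.divisor_ is None:
            raise RuntimeError("scaler not fitted")
        return np.asarray(values, dtype=float) * self.divisor_

    def fit_transform(self, values: np.ndarray) -> np.ndarray:
        return self.fit(values).transform(values)


def merged_reflectivity_feature(
    cdf9: CDFDescriptor | np.ndarray,
    glcm: GLCMFeatures | np.ndarray,
    ci_scaler: CIScaler,
    glcm_scaler: GLCMMaxScaler,
) -> np.ndarray:
    """The 13-value merged reflectivity feature of one layer:
    [p10..p90 scaled by the training CI bound, then contrast, correlation,
    energy, homogeneity scaled by their training maxima]."""
    p = cdf9.values if isinstance(cdf9, CDFDescriptor) else np.asarray(cdf9)
    g = glcm.as_array() if isinstance(glcm, GLCMFeatures) else np.asarray(glcm)
    if p.shape != (9,) or g.shape != (4,):
        raise ValueError("expected 9 percentiles and 4 GLCM features")
    return np.concatenate([ci_scaler.transform(p), glcm_scaler.transform(g)])
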