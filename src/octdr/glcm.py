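"""Global higher-order reflectivity: per-layer gray-level co-occurrence
matrices and the four classical statistics (contrast, correlation, energy,
homogeneity).

The GLCM of a layer counts how often pairs of quantized intensities occur at
8-neighbouring pixel positions where *both* pixels carry the layer's label.
Both ordered directions of every offset are accumulated (symmetric matrix),
and the matrix is normalized to a probability table before any statistic is
evaluated.  Unlike the other markers, the GLCM statistics are global per
layer: no spatial binning and no CDF summarization is applied to them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

#: the 8-neighbourhood up to point symmetry, as (row, col) offsets
NEIGHBOR_OFFSETS_8: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))

DEFAULT_Q = 8


@dataclass
class GLCM:
    """Normalized co-occurrence probability table of one layer region."""

    p: np.ndarray  # Q x Q probabilities
    Q: int
    offsets: tuple[tuple[int, int], ...]
    layer: int = 0
    n_pairs: int = 0


@dataclass
class GLCMFeatures:
    contrast: float
    correlation: float
    energy: float
    homogeneity: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.contrast, self.correlation, self.energy, self.homogeneity]
        )

    #: fixed feature order used throughout the pipeline
    NAMES = ("contrast", "correlation", "energy", "homogeneity")


def quantize(values: np.ndarray, Q: int,
             vrange: tuple[float, float] | None = None) -> np.ndarray:
    """Quantize intensities to ``Q`` uniform bins over ``vrange``.

    ``vrange`` defaults to the finite min/max of ``values`` (the scan's
    normalized-reflectivity range).  Returns integer levels in 0..Q-1.
    """
    v = np.asarray(values, dtype=float)
    if vrange is None:
        finite = v[np.isfinite(v)]
        lo, hi = float(finite.min()), float(finite.max())
    else:
        lo, hi = vrange
    if hi <= lo:  # constant image: single level
        return np.zeros_like(v, dtype=np.intp)
    levels = np.floor((v - lo) / (hi - lo) * Q).astype(np.intp)
    return np.clip(levels, 0, Q - 1)


def build_glcm(
    image: np.ndarray,
    mask: np.ndarray,
    Q: int = DEFAULT_Q,
    offsets: tuple[tuple[int, int], ...] = NEIGHBOR_OFFSETS_8,
    vrange: tuple[float, float] | None = None,
    layer: int = 0,
) -> GLCM:
    """Build the normalized 8-neighbour GLCM of a masked image region.

    A pixel pair contributes only when both members lie inside ``mask``;
    each unordered neighbour pair is counted once per direction, so the
    resulting matrix is symmetric.

    Raises
    ------
    ValueError
        If the mask holds fewer than two mutually adjacent pixels.
    """
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if Q < 2:
        raise ValueError("Q must be >= 2")
    levels = quantize(image, Q, vrange=vrange)

    counts = np.zeros((Q, Q), dtype=np.int64)
    H, W = image.shape
    for dr, dc in offsets:
        r0 = max(0, -dr); r1 = min(H, H - dr)
        c0 = max(0, -dc); c1 = min(W, W - dc)
        a = levels[r0:r1, c0:c1]
        b = levels[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        m = mask[r0:r1, c0:c1] & mask[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        if not m.any():
            continue
        # both ordered directions -> symmetric accumulation
        np.add.at(counts, (a[m], b[m]), 1)
        np.add.at(counts, (b[m], a[m]), 1)
    total = counts.sum()
    if total == 0:
        raise ValueError("degenerate layer region: no adjacent in-mask pair")
    return GLCM(p=counts / total, Q=Q, offsets=tuple(offsets), layer=layer,
                n_pairs=int(total))


def glcm_statistics(glcm: GLCM) -> GLCMFeatures:
    """Evaluate contrast, correlation, energy and homogeneity of a GLCM.

    Correlation is defined as 0 for a region whose marginal variance
    vanishes (constant region), where the textbook ratio is 0/0.
    """
    p = glcm.p
    Q = glcm.Q
    i = np.arange(Q)[:, None]
    j = np.arange(Q)[None, :]
    contrast = float(np.sum(p * np.abs(i - j) ** 2))
    energy = float(np.sum(p ** 2))
    homogeneity = float(np.sum(p / (1.0 + np.abs(i - j))))
    mu_x = float(np.sum(i * p))
    mu_y = float(np.sum(j * p))
    sigma_x = float(np.sqrt(np.sum((i - mu_x) ** 2 * p)))
    sigma_y = float(np.sqrt(np.sum((j - mu_y) ** 2 * p)))
    if sigma_x * sigma_y == 0.0:
        correlation = 0.0
    else:
        correlation = float(
            np.sum(p * (i - mu_x) * (j - mu_y)) / (sigma_x * sigma_y)
        )
    return GLCMFeatures(contrast, correlation, energy, homogeneity)


class GLCMMaxScaler:
    """Per-feature max scaler for GLCM markers, fit on training cases only.

    Each GLCM feature is divided by the maximum of that feature over all
    training cases; test values above the training maximum stay > 1 (no
    clipping).
    """

    def __init__(self) -> None:
        self.max_: np.ndarray | None = None

    def fit(self, values: np.ndarray) -> "GLCMMaxScaler":
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if values.shape[0] < 1:
            raise ValueError("need at least one training case")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            self.max_ = np.nanmax(np.abs(values), axis=0)
        if np.any(self.max_ == 0):
            warnings.warn(
                "zero training maximum for some GLCM feature; passed through "
                "unscaled", stacklevel=2,
            )
        return self

    def transform(self, values: np.ndarray) -> np.ndarray:
        if self.max_ is None:
            raise RuntimeError("scaler not fitted")
        values = np.asarray(values, dtype=float)
        denom = np.where(self.max_ == 0, 1.0, self.max_)
        return values / denom

    def fit_transform(self, values: np.ndarray) -> np.ndarray:
        return self.fit(values).transform(values)
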