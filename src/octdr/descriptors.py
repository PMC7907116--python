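"""CDF percentile descriptors of per-bin marker profiles.

Every marker except the GLCM statistics is summarized the same way: the
per-bin measurements of one layer are treated as an empirical distribution
and reduced to its 10th..90th percentiles in 10% steps.  Nine numbers per
(layer, marker), regardless of how many bins the layer supported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

#: percentile grid of the descriptor, in percent
PERCENTILES = np.arange(10, 100, 10)


@dataclass
class MarkerProfile:
    """Per-bin values of one marker in one layer.

    ``values`` may contain NaN sentinels for bins where the marker could not
    be measured (empty bin, dropped offset); they are excluded from all
    statistics.
    """

    values: np.ndarray
    layer: int = 0
    marker: str = ""
    bin_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def finite_values(self) -> np.ndarray:
        v = self.values.ravel()
        return v[np.isfinite(v)]


@dataclass
class CDFDescriptor:
    """The nine percentile summary values of one marker distribution."""

    values: np.ndarray
    layer: int = 0
    marker: str = ""
    n_finite: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (9,):
            raise ValueError("CDF descriptor must hold exactly 9 values")


def build_cdf_descriptor(profile: MarkerProfile) -> CDFDescriptor:
    """Summarize a marker profile by the 10th..90th percentiles of its CDF.

    Percentiles use linear interpolation between closest order statistics
    (``numpy``'s "linear" convention): for n values the p-th percentile is
    the order statistic at fractional rank 1 + (n-1)p/100.

    Raises
    ------
    ValueError
        If the profile holds no finite value.
    """
    finite = profile.finite_values()
    if finite.size == 0:
        raise ValueError(
            f"all-missing marker profile: layer={profile.layer} "
            f"marker={profile.marker!r}"
        )
    if finite.size < 9:
        warnings.warn(
            f"marker profile for layer {profile.layer} ({profile.marker!r}) "
            f"has only {finite.size} finite bins; percentiles are of a small "
            "sample",
            stacklevel=2,
        )
    pct = np.percentile(finite, PERCENTILES, method="linear")
    return CDFDescriptor(
        values=pct, layer=profile.layer, marker=profile.marker,
        n_finite=int(finite.size),
    )
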