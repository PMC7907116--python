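"""Local higher-order reflectivity: second-order Markov-Gibbs random field
(MGRF) Gibbs potentials and energies of a layer region.

Each layer is viewed as a sample of a translation-invariant MGRF with
pairwise cliques.  For every offset (zeta, eta) of the neighbourhood system
the empirical joint co-occurrence distribution f(q, s) over in-layer cliques
is compared with the product of marginals; the analytic maximum-likelihood
potential estimate is

    V(q, s) = rho * [f(q, s) - f(q) f(s)]

and the Gibbs energy of the clique family is

    E = sum_{q,s} f(q, s) [f(q, s) - f(q) f(s)].

The unspecified common scale rho cancels from the energy and is fixed to 1.
E vanishes exactly when the joint factorizes (independent co-occurrences)
and grows with the interaction strength, which makes it a local texture
marker.  The partition function of the full Gibbs distribution is never
needed for the marker and is not computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .glcm import quantize

#: default pairwise offsets: the 8-neighbourhood up to point symmetry,
#: expressed as (x, y) = (col, row) offsets
DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((1, 0), (0, 1), (1, 1), (1, -1))


@dataclass
class OffsetSystem:
    """Neighbourhood system of the MGRF: a set of (x, y) offsets and the
    number of gray levels Q."""

    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS
    Q: int = 8

    def __post_init__(self) -> None:
        seen = set()
        for off in self.offsets:
            if off == (0, 0):
                raise ValueError("offset (0,0) is not a pairwise clique")
            if off in seen:
                raise ValueError(f"duplicate offset {off}")
            seen.add(off)


@dataclass
class CoocDistributions:
    """Empirical marginal and joint co-occurrence distributions per offset.

    ``joint[k]`` is the Q x Q joint distribution of ordered intensity pairs
    over the cliques of offset k; ``marginal[k]`` is the distribution of
    intensities over the clique-endpoint multiset of that offset (so the
    symmetrized marginalization of the joint reproduces it exactly).
    Offsets with no in-mask clique are recorded in ``dropped``.
    """

    system: OffsetSystem
    joint: list[np.ndarray | None]
    marginal: list[np.ndarray | None]
    n_cliques: list[int]
    dropped: list[int] = field(default_factory=list)


@dataclass
class GibbsResult:
    potentials: list[np.ndarray | None]
    energies: np.ndarray  # per offset; NaN sentinel where offset dropped

    @property
    def energy_vector(self) -> np.ndarray:
        return self.energies


def estimate_cooccurrence(
    image: np.ndarray,
    mask: np.ndarray,
    system: OffsetSystem | None = None,
    vrange: tuple[float, float] | None = None,
) -> CoocDistributions:
    """Count intensity co-occurrences over cliques fully inside the mask.

    Each clique ((x, y), (x+zeta, y+eta)) whose two endpoints both carry the
    layer label contributes its ordered intensity pair (q, s).  Counts are
    normalized to probabilities; intensities are quantized to Q uniform
    levels over ``vrange`` (default: the region's own range).
    """
    if system is None:
        system = OffsetSystem()
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    levels = quantize(image, system.Q, vrange=vrange)
    H, W = image.shape
    Q = system.Q

    joints: list[np.ndarray | None] = []
    marginals: list[np.ndarray | None] = []
    n_cliques: list[int] = []
    dropped: list[int] = []
    for k, (zeta, eta) in enumerate(system.offsets):
        dc, dr = zeta, eta  # offsets are (x, y) = (col, row)
        r0 = max(0, -dr); r1 = min(H, H - dr)
        c0 = max(0, -dc); c1 = min(W, W - dc)
        if r0 >= r1 or c0 >= c1:
            joints.append(None); marginals.append(None); n_cliques.append(0)
            dropped.append(k)
            continue
        a = levels[r0:r1, c0:c1]
        b = levels[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        m = mask[r0:r1, c0:c1] & mask[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        n = int(m.sum())
        if n == 0:
            warnings.warn(
                f"offset {(zeta, eta)} has no in-mask clique; dropped",
                stacklevel=2,
            )
            joints.append(None); marginals.append(None); n_cliques.append(0)
            dropped.append(k)
            continue
        jcounts = np.zeros((Q, Q), dtype=np.int64)
        np.add.at(jcounts, (a[m], b[m]), 1)
        joint = jcounts / n
        # marginal over the clique-endpoint multiset = symmetrized joint sums
        marginal = 0.5 * (joint.sum(axis=1) + joint.sum(axis=0))
        joints.append(joint); marginals.append(marginal); n_cliques.append(n)
    return CoocDistributions(system=system, joint=joints, marginal=marginals,
                             n_cliques=n_cliques, dropped=dropped)


def gibbs_potentials(dists: CoocDistributions, rho: float = 1.0
                     ) -> list[np.ndarray | None]:
    """Analytic ML estimate of pairwise Gibbs potentials per offset:
    V(q, s) = rho * [f(q, s) - f(q) f(s)]."""
    out: list[np.ndarray | None] = []
    for joint, marg in zip(dists.joint, dists.marginal):
        if joint is None:
            out.append(None)
            continue
        out.append(rho * (joint - np.outer(marg, marg)))
    return out


def gibbs_energy(dists: CoocDistributions) -> GibbsResult:
    """Gibbs energy per clique family:
    E = sum f(q,s) [f(q,s) - f(q) f(s)].  Dropped offsets yield NaN."""
    pots = gibbs_potentials(dists, rho=1.0)
    energies = np.full(len(dists.joint), np.nan)
    for k, (joint, V) in enumerate(zip(dists.joint, pots)):
        if joint is None:
            continue
        energies[k] = float(np.sum(joint * V))
    return GibbsResult(potentials=pots, energies=energies)


def layer_gibbs_energy(
    image: np.ndarray,
    mask: np.ndarray,
    system: OffsetSystem | None = None,
    vrange: tuple[float, float] | None = None,
) -> float:
    """Scalar Gibbs-energy marker of a layer: mean energy over the offsets
    of the neighbourhood system (NaN-aware)."""
    dists = estimate_cooccurrence(image, mask, system=system, vrange=vrange)
    res = gibbs_energy(dists)
    finite = res.energies[np.isfinite(res.energies)]
    if finite.size == 0:
        return float("nan")
    return float(finite.mean())


def binned_gibbs_energy(
    image: np.ndarray,
    mask: np.ndarray,
    n_bins: int,
    system: OffsetSystem | None = None,
    vrange: tuple[float, float] | None = None,
) -> np.ndarray:
    """Per-bin Gibbs-energy profile of a layer.

    The layer's occupied column span is split into ``n_bins`` contiguous
    column groups; the energy marker is evaluated inside each group (summed
    over the offset system).  Bins without enough cliques yield NaN, to be
    excluded by the CDF descriptor.
    """
    mask = np.asarray(mask, dtype=bool)
    cols = np.flatnonzero(mask.any(axis=0))
    out = np.full(n_bins, np.nan)
    if cols.size == 0:
        return out
    edges = np.linspace(cols[0], cols[-1] + 1, n_bins + 1).astype(int)
    for b in range(n_bins):
        sub = np.zeros_like(mask)
        sub[:, edges[b]:edges[b + 1]] = mask[:, edges[b]:edges[b + 1]]
        if not sub.any():
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            e = layer_gibbs_energy(image, sub, system=system, vrange=vrange)
        out[b] = e
    return out
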