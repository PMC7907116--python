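"""Synthetic layered-retina phantoms.

Generates labeled OCT-like B-scans so that every downstream stage
(segmentation, markers, classification) can be exercised against a known
ground truth.  A phantom is a stack of twelve smooth layer bands between a
dark vitreous (top) and a mid-gray choroid (bottom): a shallow global
curvature bows the retina, and a centred foveal pit thins the inner five
layers (NFL..OPL) toward the centre, emulating their anatomical vanishing
at the fovea.  Disease-like (DR) scans add per-layer thickness and
reflectivity offsets plus a sinusoidal displacement of all boundaries that
raises boundary tortuosity without breaking the layer ordering.

The generator is deliberately simple optics-wise: speckle is modeled as
multiplicative unit-mean gamma noise (or additive Gaussian), not as a
physical interference pattern, and no vascular shadowing or 3-D effects are
simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: anatomical layer names, label 1..12 from the vitreous side down
LAYER_NAMES = (
    "NFL", "GCL", "IPL", "INL", "OPL", "ONL",
    "ELM", "MZ", "EZ", "OPR", "IZ", "RPE",
)

#: indices (1-based labels) of the inner five layers that thin at the fovea
INNER_FIVE = (1, 2, 3, 4, 5)

DEFAULT_THICKNESS = (12.0, 10.0, 10.0, 8.0, 7.0, 16.0, 3.0, 4.0, 4.0, 5.0, 4.0, 7.0)
DEFAULT_REFLECTIVITY = (170.0, 90.0, 120.0, 80.0, 115.0, 55.0,
                        110.0, 70.0, 190.0, 125.0, 145.0, 200.0)


@dataclass
class DREffect:
    """Disease-like perturbations applied to DR-class scans."""

    thickness_delta: tuple[float, ...] = (0, 0, 0, 2.0, 0, 5.0, 0, 0, 0, 0, 0, 0)
    reflectivity_delta: tuple[float, ...] = (-12.0, -6.0, 0, 0, 0, -8.0,
                                             0, 0, 0, 0, 0, 0)
    tortuosity_amplitude: float = 2.0   # px
    tortuosity_frequency: float = 4.0   # cycles per image width
    #: DR tissue shows more heterogeneous backscatter: intra-retinal noise
    #: is scaled up and spatially correlated (clumped), which gives the
    #: local-texture (Gibbs energy) marker a class signal
    noise_scale_factor: float = 1.3
    noise_correlation_length: float = 1.0  # px, 0 = independent speckle


@dataclass
class PhantomConfig:
    image_height: int = 160
    image_width: int = 256
    layer_mean_thickness: tuple[float, ...] = DEFAULT_THICKNESS
    layer_mean_reflectivity: tuple[float, ...] = DEFAULT_REFLECTIVITY
    vitreous_reflectivity: float = 10.0
    choroid_reflectivity: float = 60.0
    foveal_pit_depth: float = 45.0      # px removed from the inner five at centre
    foveal_pit_width: float = 80.0      # px
    curvature_amplitude: float = 8.0    # px bow of the whole retina
    top_margin_fraction: float = 0.2    # vitreous depth of the upper surface
    noise_model: str = "multiplicative-speckle"  # or "additive-gaussian"
    noise_scale: float = 0.08   # speckle: fractional std; gaussian: gray levels
    bit_depth: int = 8
    dr_effect: DREffect = field(default_factory=DREffect)
    seed: int = 0

    def validate(self) -> None:
        if len(self.layer_mean_thickness) != 12 or len(self.layer_mean_reflectivity) != 12:
            raise ValueError("exactly 12 layer thicknesses/reflectivities required")
        if any(t <= 0 for t in self.layer_mean_thickness):
            raise ValueError("all layer thicknesses must be positive")
        vmax = 2 ** self.bit_depth - 1
        for v in (*self.layer_mean_reflectivity, self.vitreous_reflectivity,
                  self.choroid_reflectivity):
            if not (0 <= v <= vmax):
                raise ValueError(f"reflectivity {v} outside bit depth 0..{vmax}")
        if self.foveal_pit_width >= self.image_width:
            raise ValueError("foveal pit wider than the image")
        if self.noise_model not in ("multiplicative-speckle", "additive-gaussian"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.noise_scale < 0:
            raise ValueError("noise scale must be non-negative")


@dataclass
class PhantomScan:
    image: np.ndarray           # float gray values, clamped to bit depth
    truth_labels: np.ndarray    # int, 0 outside retina, 1..12 = NFL..RPE
    class_label: str            # "normal" | "DR"
    subject_id: str = "s000"
    eye: str = "OD"
    boundaries: np.ndarray | None = None  # (13, width) generating band edges


def _scan_rng(seed: int, index: int = 0) -> np.random.Generator:
    """Per-scan RNG: master seed plus a scan counter (spawn-key scheme)."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def layer_boundaries(config: PhantomConfig, class_label: str) -> np.ndarray:
    """Generating band edges b[k, x], k = 0..12, of the phantom's layers.

    Pixels of column x with centre row in [b[k-1, x], b[k, x]) carry label k.
    """
    config.validate()
    W = config.image_width
    x = np.arange(W, dtype=float)
    cx = (W - 1) / 2.0

    thick = np.array(config.layer_mean_thickness, dtype=float)
    if class_label == "DR":
        thick = np.maximum(thick + np.asarray(config.dr_effect.thickness_delta), 0.5)

    top = (config.top_margin_fraction * config.image_height
           + config.curvature_amplitude * ((x - cx) / (W / 2.0)) ** 2)

    # foveal pit: the inner five layers shed `pit(x)` pixels of thickness,
    # distributed proportionally, so the upper surface dips at the centre
    sigma = config.foveal_pit_width / 4.0
    pit = config.foveal_pit_depth * np.exp(-0.5 * ((x - cx) / sigma) ** 2)
    inner_sum = thick[[k - 1 for k in INNER_FIVE]].sum()
    shrink = np.clip(1.0 - pit / inner_sum, 0.02, 1.0)

    t = np.tile(thick[:, None], (1, W))
    for k in INNER_FIVE:
        t[k - 1] *= shrink
    # the pit is a dip of the top surface: outer layers keep their depth
    top = top + (inner_sum - t[[k - 1 for k in INNER_FIVE]].sum(axis=0))

    b = np.empty((13, W))
    b[0] = top
    np.cumsum(t, axis=0, out=b[1:])
    b[1:] += top

    if class_label == "DR" and config.dr_effect.tortuosity_amplitude > 0:
        A = config.dr_effect.tortuosity_amplitude
        f = config.dr_effect.tortuosity_frequency
        b += A * np.sin(2 * np.pi * f * x / W)[None, :]
    return b


def generate_scan(config: PhantomConfig, class_label: str = "normal",
                  subject_id: str = "s000", eye: str = "OD",
                  scan_index: int = 0) -> PhantomScan:
    """Generate one phantom B-scan with its ground-truth label map.

    Identical (config, class_label, scan_index) gives bit-identical output.
    DR-specific deltas in ``config.dr_effect`` are ignored for normal scans.
    """
    if class_label not in ("normal", "DR"):
        raise ValueError(f"unknown class label {class_label!r}")
    b = layer_boundaries(config, class_label)
    H, W = config.image_height, config.image_width

    refl = np.array(config.layer_mean_reflectivity, dtype=float)
    if class_label == "DR":
        refl = refl + np.asarray(config.dr_effect.reflectivity_delta)

    rows = np.arange(H, dtype=float)[:, None] + 0.5
    labels = np.zeros((H, W), dtype=np.int16)
    image = np.full((H, W), config.vitreous_reflectivity, dtype=float)
    below = rows >= b[12][None, :]
    image[below] = config.choroid_reflectivity
    for k in range(1, 13):
        band = (rows >= b[k - 1][None, :]) & (rows < b[k][None, :])
        labels[band] = k
        image[band] = refl[k - 1]

    rng = _scan_rng(config.seed, scan_index)
    s = config.noise_scale
    if s > 0:
        # intra-retinal noise of DR scans is stronger and spatially
        # correlated (heterogeneous, clumped backscatter of diseased
        # tissue); elsewhere the speckle field is independent per pixel
        z = rng.standard_normal(image.shape)
        smap = np.full(image.shape, s)
        if class_label == "DR":
            retina = labels > 0
            smap[retina] *= config.dr_effect.noise_scale_factor
            corr = config.dr_effect.noise_correlation_length
            if corr > 0:
                from scipy import ndimage
                zc = ndimage.gaussian_filter(z, corr)
                zc = zc / zc.std()
                z = np.where(retina, zc, z)
        if config.noise_model == "multiplicative-speckle":
            # unit-mean lognormal speckle with fractional std ~ smap
            sig = np.sqrt(np.log1p(smap ** 2))
            image = image * np.exp(sig * z - 0.5 * sig ** 2)
        else:
            image = image + smap * z
    vmax = 2 ** config.bit_depth - 1
    np.clip(image, 0, vmax, out=image)
    return PhantomScan(image=image, truth_labels=labels,
                       class_label=class_label, subject_id=subject_id,
                       eye=eye, boundaries=b)


def _jitter_config(config: PhantomConfig, rng: np.random.Generator,
                   subject_seed: int) -> PhantomConfig:
    """Per-subject anatomical jitter: thickness +-10%, reflectivity +-5 gray,
    pit depth/width +-10%, curvature +-20%."""
    thick = tuple(t * rng.uniform(0.9, 1.1) for t in config.layer_mean_thickness)
    vmax = 2 ** config.bit_depth - 1
    refl = tuple(float(np.clip(r + rng.uniform(-5, 5), 0, vmax))
                 for r in config.layer_mean_reflectivity)
    return replace(
        config,
        layer_mean_thickness=thick,
        layer_mean_reflectivity=refl,
        foveal_pit_depth=config.foveal_pit_depth * rng.uniform(0.9, 1.1),
        foveal_pit_width=config.foveal_pit_width * rng.uniform(0.9, 1.1),
        curvature_amplitude=config.curvature_amplitude * rng.uniform(0.8, 1.2),
        seed=subject_seed,
    )


def generate_cohort(
    config: PhantomConfig,
    n_subjects: int,
    dr_fraction: float = 0.5,
    scans_per_subject: int = 2,
) -> tuple[list[PhantomScan], pd.DataFrame]:
    """Generate a cohort of phantom subjects with per-subject jittered
    anatomy, so scans of one subject correlate.

    Exactly ``round(n_subjects * dr_fraction)`` subjects are DR; all scans
    of a subject share its class.  The manifest carries one row per scan
    with columns subject_id, eye, scan_index, class.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if not 0.0 < dr_fraction < 1.0:
        raise ValueError("dr_fraction must be in (0, 1)")
    if scans_per_subject < 1:
        raise ValueError("scans_per_subject must be >= 1")
    n_dr = int(round(n_subjects * dr_fraction))
    classes = ["DR"] * n_dr + ["normal"] * (n_subjects - n_dr)

    master = np.random.default_rng(np.random.SeedSequence(config.seed))
    scans: list[PhantomScan] = []
    rows = []
    for i, cls in enumerate(classes):
        subject_seed = int(master.integers(0, 2 ** 31 - 1))
        sub_cfg = _jitter_config(config, master, subject_seed)
        sid = f"s{i:03d}"
        for j in range(scans_per_subject):
            eye = "OD" if j % 2 == 0 else "OS"
            scan = generate_scan(sub_cfg, cls, subject_id=sid, eye=eye,
                                 scan_index=j)
            scans.append(scan)
            rows.append({"subject_id": sid, "eye": eye, "scan_index": j,
                         "class": cls})
    manifest = pd.DataFrame(rows)
    return scans, manifest
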