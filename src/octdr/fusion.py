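"""Three-stage classifier: per-marker linear SVMs per layer, a per-layer
fusion BNN (49 hidden units) over the four marker probabilities, and a
global fusion BNN (30 hidden units) over the twelve layer probabilities.

Stage-1 probabilities come from Platt-style sigmoid calibration of the
linear SVM decision values; the probabilities that train the fusion stages
are produced out-of-fold by internal grouped 5-fold stacking on the
training set, so no fusion network ever sees a probability produced by a
model that was trained on the same scan (leakage control).  DR is the
positive class throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GroupKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .descriptors import MarkerProfile, build_cdf_descriptor
from .glcm import GLCMMaxScaler, build_glcm, glcm_statistics
from .mgrf import OffsetSystem, binned_gibbs_energy
from .morphology import (layer_boundary_polylines, layer_thickness_profile,
                         layer_tortuosity_marker)
from .nnet import BNN, BNNParams
from .reflectivity import (CIScaler, first_order_reflectivity,
                           merged_reflectivity_feature, normalize_scan)

MARKERS = ("gibbs", "thickness", "tortuosity", "reflectivity")
N_LAYERS = 12
POSITIVE = "DR"


# ==========================================================================
# Per-scan feature extraction
# ==========================================================================

@dataclass
class FeatureConfig:
    n_bins: int = 10            # spatial bins for gibbs/thickness/tortuosity
    bins_per_side: int = 10     # 1st-order reflectivity bins per side
    fovea_exclusion: float = 0.15
    Q: int = 8
    tortuosity_window: int = 5
    thickness_seeds: int = 60
    laplace_tol: float = 1e-4


@dataclass
class LayerFeatureSet:
    """Raw (unscaled) marker descriptors of all twelve layers of one scan.

    ``refl_cdf9`` and ``glcm4`` stay separate until training-fold scalers
    merge them into the 13-value reflectivity feature.
    """

    gibbs: np.ndarray        # (12, 9)
    thickness: np.ndarray    # (12, 9)
    tortuosity: np.ndarray   # (12, 9)
    refl_cdf9: np.ndarray    # (12, 9)
    glcm4: np.ndarray        # (12, 4)
    scan_id: str = ""
    class_label: str | None = None
    subject_id: str = ""


def extract_layer_features(pixels: np.ndarray, labels: np.ndarray,
                           config: FeatureConfig | None = None,
                           scan_id: str = "", subject_id: str = "",
                           class_label: str | None = None
                           ) -> LayerFeatureSet:
    """Extract the four marker descriptors of every layer of one scan.

    Markers that cannot be measured for a layer (layer absent, degenerate
    region) are NaN and later imputed from training-fold medians.
    """
    cfg = config or FeatureConfig()
    nscan = normalize_scan(pixels, labels)
    system = OffsetSystem(Q=cfg.Q)
    vrange = (float(np.nanmin(nscan.values)), float(np.nanmax(nscan.values)))

    gibbs = np.full((N_LAYERS, 9), np.nan)
    thick = np.full((N_LAYERS, 9), np.nan)
    tort = np.full((N_LAYERS, 9), np.nan)
    refl = np.full((N_LAYERS, 9), np.nan)
    glcm4 = np.full((N_LAYERS, 4), np.nan)

    for layer in range(1, N_LAYERS + 1):
        i = layer - 1
        mask = labels == layer
        if not mask.any():
            warnings.warn(f"layer {layer} absent; features imputed later",
                          stacklevel=2)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                prof = binned_gibbs_energy(nscan.values, mask, cfg.n_bins,
                                           system=system, vrange=vrange)
                gibbs[i] = build_cdf_descriptor(
                    MarkerProfile(prof, layer, "gibbs")).values
            except ValueError:
                pass
            try:
                tprof = layer_thickness_profile(
                    labels, layer, n_bins=cfg.n_bins,
                    n_seeds=cfg.thickness_seeds, tol=cfg.laplace_tol)
                thick[i] = build_cdf_descriptor(tprof).values
            except (ValueError, RuntimeError):
                pass
            try:
                up, lo = layer_boundary_polylines(labels, layer)
                marker = layer_tortuosity_marker(
                    up, lo, window=cfg.tortuosity_window,
                    n_bins=cfg.n_bins, layer=layer)
                tort[i] = build_cdf_descriptor(marker).values
            except ValueError:
                pass
            try:
                rprof = first_order_reflectivity(
                    nscan, labels, layer, bins_per_side=cfg.bins_per_side,
                    fovea_exclusion=cfg.fovea_exclusion)
                refl[i] = build_cdf_descriptor(rprof).values
            except ValueError:
                pass
            try:
                g = build_glcm(nscan.values, mask, Q=cfg.Q, vrange=vrange,
                               layer=layer)
                glcm4[i] = glcm_statistics(g).as_array()
            except ValueError:
                pass
    return LayerFeatureSet(gibbs=gibbs, thickness=thick, tortuosity=tort,
                           refl_cdf9=refl, glcm4=glcm4, scan_id=scan_id,
                           subject_id=subject_id, class_label=class_label)


# ==========================================================================
# Stage 1: calibrated linear SVM per (layer, marker)
# ==========================================================================

class CalibratedLinearSVM:
    """Linear-kernel SVM with Platt-style sigmoid probability calibration.

    The sigmoid is a logistic regression fitted on decision values that may
    come from out-of-fold models (stacking) rather than resubstitution.
    After fitting, only plain parameter arrays are kept (feature
    standardization, hyperplane, sigmoid), so models persist as arrays.
    """

    def __init__(self, C: float = 1.0, seed: int = 0) -> None:
        self.C = C
        self.seed = seed
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None
        self.coef_: np.ndarray | None = None
        self.intercept_: float = 0.0
        self.platt_a_: float = 1.0
        self.platt_b_: float = 0.0
        self.platt = LogisticRegression(C=1e6)

    def fit(self, X: np.ndarray, y: np.ndarray,
            calib_scores: np.ndarray | None = None,
            calib_y: np.ndarray | None = None) -> "CalibratedLinearSVM":
        if np.unique(y).size < 2:
            raise ValueError("single-class training input")
        scaler = StandardScaler().fit(X)
        Xs = scaler.transform(X)
        svm = SVC(kernel="linear", C=self.C, random_state=self.seed)
        svm.fit(Xs, y)
        self.mean_ = scaler.mean_
        self.scale_ = scaler.scale_
        self.coef_ = svm.coef_.ravel()
        self.intercept_ = float(svm.intercept_[0])
        if calib_scores is None:
            calib_scores = self.decision_function(X)
            calib_y = y
        self.platt.fit(np.asarray(calib_scores).reshape(-1, 1),
                       np.asarray(calib_y))
        self.platt_a_ = float(self.platt.coef_[0, 0])
        self.platt_b_ = float(self.platt.intercept_[0])
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        return Xs @ self.coef_ + self.intercept_

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        d = self.decision_function(X)
        return 1.0 / (1.0 + np.exp(-(self.platt_a_ * d + self.platt_b_)))

    def to_arrays(self) -> dict:
        return {"mean": self.mean_, "scale": self.scale_,
                "coef": self.coef_,
                "intercept_platt": np.array([self.intercept_, self.platt_a_,
                                             self.platt_b_])}

    @classmethod
    def from_arrays(cls, arrays: dict) -> "CalibratedLinearSVM":
        clf = cls()
        clf.mean_ = np.asarray(arrays["mean"])
        clf.scale_ = np.asarray(arrays["scale"])
        clf.coef_ = np.asarray(arrays["coef"])
        clf.intercept_, clf.platt_a_, clf.platt_b_ = [
            float(v) for v in arrays["intercept_platt"]]
        return clf


def _oof_decision_values(X: np.ndarray, y: np.ndarray, groups: np.ndarray,
                         n_splits: int = 5, C: float = 1.0,
                         seed: int = 0) -> np.ndarray:
    """Out-of-fold SVM decision values via grouped K-fold stacking."""
    n_groups = np.unique(groups).size
    n_splits = min(n_splits, n_groups)
    oof = np.zeros(len(y))
    gkf = GroupKFold(n_splits=n_splits)
    scaler = StandardScaler()
    for tr, te in gkf.split(X, y, groups):
        if np.unique(y[tr]).size < 2:
            oof[te] = 0.0
            continue
        Xt = scaler.fit_transform(X[tr])
        svm = SVC(kernel="linear", C=C, random_state=seed)
        svm.fit(Xt, y[tr])
        oof[te] = svm.decision_function(scaler.transform(X[te]))
    return oof


# ==========================================================================
# Fusion model
# ==========================================================================

@dataclass
class Diagnosis:
    layer_probabilities: np.ndarray   # (12,) DR probability per layer
    global_probability: float         # DR probability of the B-scan
    predicted_class: str              # at threshold 0.5; ties -> DR

    def __post_init__(self) -> None:
        probs = np.append(self.layer_probabilities, self.global_probability)
        if np.any((probs < 0) | (probs > 1)):
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class FusionConfig:
    layer_hidden: int = 49
    global_hidden: int = 30
    markers: tuple[str, ...] = MARKERS
    svm_C: float = 1.0
    stacking_folds: int = 5
    bnn: BNNParams = field(default_factory=BNNParams)
    seed: int = 0


class FusionModel:
    """12x4 calibrated SVMs + 12 layer-fusion BNNs + 1 global BNN."""

    def __init__(self, config: FusionConfig | None = None) -> None:
        self.config = config or FusionConfig()
        self.svms: dict[tuple[int, str], CalibratedLinearSVM] = {}
        self.layer_nets: list[BNN] = []
        self.global_net: BNN | None = None
        self.ci_scalers: list[CIScaler] = []
        self.glcm_scalers: list[GLCMMaxScaler] = []
        self.imputation_medians: dict[tuple[int, str], np.ndarray] = {}
        self.train_scan_ids: list[str] = []

    # ---- feature assembly ----------------------------------------------

    def _marker_matrix(self, features: list[LayerFeatureSet], layer_idx: int,
                       marker: str, fit_scalers: bool = False) -> np.ndarray:
        if marker == "reflectivity":
            cdf = np.stack([f.refl_cdf9[layer_idx] for f in features])
            glcm = np.stack([f.glcm4[layer_idx] for f in features])
            if fit_scalers:
                self.ci_scalers[layer_idx].fit(cdf)
                self.glcm_scalers[layer_idx].fit(glcm)
            return np.stack([
                merged_reflectivity_feature(
                    c, g, self.ci_scalers[layer_idx],
                    self.glcm_scalers[layer_idx])
                for c, g in zip(cdf, glcm)])
        return np.stack([getattr(f, marker)[layer_idx] for f in features])

    def _impute(self, X: np.ndarray, key: tuple[int, str],
                fit: bool) -> np.ndarray:
        if fit:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                med = np.nanmedian(X, axis=0)
            med = np.nan_to_num(med)
            self.imputation_medians[key] = med
        med = self.imputation_medians[key]
        X = np.where(np.isfinite(X), X, med[None, :])
        return X

    # ---- training -------------------------------------------------------

    def fit(self, features: list[LayerFeatureSet]) -> "FusionModel":
        """Train all three stages on a list of per-scan feature sets."""
        cfg = self.config
        y = np.array([1 if f.class_label == POSITIVE else 0 for f in features])
        if np.unique(y).size < 2:
            raise ValueError("single-class training input")
        groups = np.array([f.subject_id for f in features])
        self.train_scan_ids = [f.scan_id for f in features]
        self.ci_scalers = [CIScaler() for _ in range(N_LAYERS)]
        self.glcm_scalers = [GLCMMaxScaler() for _ in range(N_LAYERS)]

        # stage 1: per (layer, marker) SVM with OOF stacking
        markers = cfg.markers
        oof_probs = np.zeros((len(features), N_LAYERS, len(markers)))
        for li in range(N_LAYERS):
            for mi, marker in enumerate(markers):
                X = self._marker_matrix(features, li, marker,
                                        fit_scalers=True)
                X = self._impute(X, (li, marker), fit=True)
                oof_d = _oof_decision_values(
                    X, y, groups, n_splits=cfg.stacking_folds, C=cfg.svm_C,
                    seed=cfg.seed)
                clf = CalibratedLinearSVM(C=cfg.svm_C, seed=cfg.seed)
                clf.fit(X, y, calib_scores=oof_d, calib_y=y)
                self.svms[(li, marker)] = clf
                oof_probs[:, li, mi] = clf.platt.predict_proba(
                    oof_d.reshape(-1, 1))[:, 1]

        # stage 2: one BNN per layer on the OOF marker probabilities
        self.layer_nets = []
        layer_out = np.zeros((len(features), N_LAYERS))
        for li in range(N_LAYERS):
            net = BNN(len(markers), cfg.layer_hidden, 2, params=cfg.bnn,
                      seed=cfg.seed + li)
            net.fit(oof_probs[:, li, :], y)
            self.layer_nets.append(net)
            layer_out[:, li] = net.predict_proba(oof_probs[:, li, :])[:, 1]

        # stage 3: global BNN on the twelve layer probabilities
        self.global_net = BNN(N_LAYERS, cfg.global_hidden, 2,
                              params=cfg.bnn, seed=cfg.seed + 100)
        self.global_net.fit(layer_out, y)
        return self

    # ---- prediction -----------------------------------------------------

    def marker_probabilities(self, features: list[LayerFeatureSet]
                             ) -> np.ndarray:
        """Stage-1 DR probabilities, shape (n_scans, 12, 4)."""
        markers = self.config.markers
        out = np.zeros((len(features), N_LAYERS, len(markers)))
        for li in range(N_LAYERS):
            for mi, marker in enumerate(markers):
                X = self._marker_matrix(features, li, marker)
                if not np.all(np.isfinite(X)):
                    warnings.warn("missing marker values imputed at predict "
                                  "time", stacklevel=2)
                X = self._impute(X, (li, marker), fit=False)
                out[:, li, mi] = self.svms[(li, marker)].predict_proba(X)
        return out

    def fuse_layer(self, layer_idx: int, marker_probs: np.ndarray
                   ) -> np.ndarray:
        """Stage-2 fusion of the four marker probabilities of one layer."""
        p = np.atleast_2d(np.asarray(marker_probs, dtype=float))
        n_markers = len(self.config.markers)
        if p.shape[1] != n_markers:
            raise ValueError(f"expected {n_markers} marker probabilities")
        if not np.all(np.isfinite(p)):
            warnings.warn("missing marker probability imputed with 0.5",
                          stacklevel=2)
            p = np.where(np.isfinite(p), p, 0.5)
        return self.layer_nets[layer_idx].predict_proba(p)[:, 1]

    def fuse_global(self, layer_probs: np.ndarray) -> Diagnosis:
        """Stage-3 fusion of the twelve layer probabilities into the final
        diagnosis; ties at 0.5 resolve to DR (the sensitive choice)."""
        p = np.asarray(layer_probs, dtype=float).reshape(1, -1)
        if p.shape[1] != N_LAYERS:
            raise ValueError(f"expected {N_LAYERS} layer probabilities")
        g = float(self.global_net.predict_proba(p)[0, 1])
        return Diagnosis(layer_probabilities=np.asarray(layer_probs, float),
                         global_probability=g,
                         predicted_class=POSITIVE if g >= 0.5 else "normal")

    # ---- persistence ----------------------------------------------------

    def save(self, path) -> None:
        """Persist the model as a directory: one NPZ of parameter arrays
        plus a JSON architecture description."""
        import json
        from pathlib import Path

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        arrays: dict[str, np.ndarray] = {}
        for (li, marker), clf in self.svms.items():
            for k, v in clf.to_arrays().items():
                arrays[f"svm_{li}_{marker}_{k}"] = v
        for li, net in enumerate(self.layer_nets):
            for k, v in net.state_dict().items():
                if isinstance(v, np.ndarray):
                    arrays[f"layer{li}_{k}"] = v
        for k, v in self.global_net.state_dict().items():
            if isinstance(v, np.ndarray):
                arrays[f"global_{k}"] = v
        for li in range(N_LAYERS):
            arrays[f"ci_{li}"] = self.ci_scalers[li].divisor_
            arrays[f"glcmmax_{li}"] = self.glcm_scalers[li].max_
        for (li, marker), med in self.imputation_medians.items():
            arrays[f"impute_{li}_{marker}"] = med
        np.savez(path / "parameters.npz", **arrays)
        arch = {
            "markers": list(self.config.markers),
            "n_layers": N_LAYERS,
            "layer_hidden": self.config.layer_hidden,
            "global_hidden": self.config.global_hidden,
            "svm_C": self.config.svm_C,
            "seed": self.config.seed,
            "train_scan_ids": self.train_scan_ids,
        }
        with open(path / "architecture.json", "w") as fh:
            json.dump(arch, fh, indent=2)

    @classmethod
    def load(cls, path) -> "FusionModel":
        import json
        from pathlib import Path

        from .reflectivity import CIScaler

        path = Path(path)
        with open(path / "architecture.json") as fh:
            arch = json.load(fh)
        npz = np.load(path / "parameters.npz")
        model = cls(FusionConfig(layer_hidden=arch["layer_hidden"],
                                 global_hidden=arch["global_hidden"],
                                 svm_C=arch["svm_C"], seed=arch["seed"],
                                 markers=tuple(arch["markers"])))
        model.train_scan_ids = arch["train_scan_ids"]
        model.ci_scalers = []
        model.glcm_scalers = []
        for li in range(N_LAYERS):
            ci = CIScaler()
            ci.divisor_ = npz[f"ci_{li}"]
            model.ci_scalers.append(ci)
            gm = GLCMMaxScaler()
            gm.max_ = npz[f"glcmmax_{li}"]
            model.glcm_scalers.append(gm)
            for marker in model.config.markers:
                model.svms[(li, marker)] = CalibratedLinearSVM.from_arrays({
                    k: npz[f"svm_{li}_{marker}_{k}"]
                    for k in ("mean", "scale", "coef", "intercept_platt")})
                model.imputation_medians[(li, marker)] = \
                    npz[f"impute_{li}_{marker}"]

        def load_net(prefix, n_in, n_hidden):
            return BNN.from_state({
                "n_in": n_in, "n_hidden": n_hidden, "n_out": 2,
                **{k: npz[f"{prefix}_{k}"] for k in ("W1", "b1", "W2",
                                                     "b2")}})

        model.layer_nets = [load_net(f"layer{li}", len(model.config.markers),
                                     arch["layer_hidden"])
                            for li in range(N_LAYERS)]
        model.global_net = load_net("global", N_LAYERS,
                                    arch["global_hidden"])
        return model

    def predict(self, features: list[LayerFeatureSet]) -> list[Diagnosis]:
        mp = self.marker_probabilities(features)
        out = []
        for i in range(len(features)):
            lp = np.array([self.fuse_layer(li, mp[i, li])[0]
                           for li in range(N_LAYERS)])
            out.append(self.fuse_global(lp))
        return out


# ==========================================================================
# Color-coded layer maps
# ==========================================================================

def render_layer_map(pixels: np.ndarray, labels: np.ndarray,
                     layer_probabilities: np.ndarray) -> np.ndarray:
    """Color-code each layer by its diagnosis: blue scale for normal, red
    for DR, darkness proportional to the winning probability in [0.5, 1];
    background stays grayscale.  Returns an (H, W, 3) float RGB image."""
    pixels = np.asarray(pixels, dtype=float)
    labels = np.asarray(labels)
    p = np.asarray(layer_probabilities, dtype=float)
    gray = (pixels - pixels.min()) / max(pixels.max() - pixels.min(), 1e-9)
    rgb = np.stack([gray] * 3, axis=-1)
    for li in range(N_LAYERS):
        mask = labels == li + 1
        if not mask.any():
            continue
        prob = p[li]
        dr = prob >= 0.5
        win = prob if dr else 1.0 - prob
        depth = np.clip((win - 0.5) / 0.5, 0.0, 1.0)  # 0.5 -> lightest
        light = 1.0 - 0.8 * depth
        color = np.array([1.0, light, light]) if dr \
            else np.array([light, light, 1.0])
        rgb[mask] = color
    return rgb
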