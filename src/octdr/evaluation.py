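"""Subject-grouped cross-validation, diagnostic metrics and experiment
reports.

Folds are always formed at the subject level (all scans of one subject stay
together) and class-stratified for K-fold; LOSO assigns one subject per
fold.  DR is the positive class: sensitivity = TP/(TP+FN) counts DR scans
identified correctly, specificity = TN/(TN+FP) normal ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .fusion import POSITIVE, FusionConfig, FusionModel, LayerFeatureSet


@dataclass
class FoldScheme:
    kind: str                       # "kfold" | "LOSO"
    k: int
    assignment: dict[str, int]      # subject_id -> fold index
    seed: int = 0

    def fold_of(self, subject_id: str) -> int:
        return self.assignment[subject_id]


def make_folds(manifest: pd.DataFrame, scheme: str, seed: int = 0
               ) -> FoldScheme:
    """Build a subject-level fold assignment.

    ``scheme`` is "loso" or "k<N>" (e.g. "k2", "k10").  K-fold assignment
    is class-stratified within +-1 subject by dealing the shuffled subjects
    of each class round-robin over the folds.
    """
    if "subject_id" not in manifest.columns or "class" not in manifest.columns:
        raise ValueError("manifest must carry subject_id and class")
    subjects = manifest.drop_duplicates("subject_id")
    sids = subjects["subject_id"].tolist()
    classes = subjects["class"].tolist()
    scheme = scheme.lower()
    if scheme == "loso":
        return FoldScheme(kind="LOSO", k=len(sids),
                          assignment={s: i for i, s in enumerate(sids)},
                          seed=seed)
    if not scheme.startswith("k"):
        raise ValueError(f"unknown scheme {scheme!r}")
    k = int(scheme[1:])
    if k > len(sids):
        raise ValueError(f"k={k} exceeds the {len(sids)} subjects")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    for cls in sorted(set(classes)):
        members = [s for s, c in zip(sids, classes) if c == cls]
        members = [members[i] for i in rng.permutation(len(members))]
        for i, s in enumerate(members):
            assignment[s] = i % k
    return FoldScheme(kind="kfold", k=k, assignment=assignment, seed=seed)


@dataclass
class MetricsReport:
    TP: int
    TN: int
    FP: int
    FN: int
    sensitivity: float      # %
    specificity: float      # %
    f1: float               # %
    accuracy: float         # %
    auc: float | None = None  # %
    per_fold: list[dict] = field(default_factory=list)
    mean_std: dict[str, tuple[float, float]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "TP": self.TP, "TN": self.TN, "FP": self.FP, "FN": self.FN,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "f1": self.f1, "accuracy": self.accuracy, "auc": self.auc,
            "per_fold": self.per_fold, "mean_std": self.mean_std,
        }


def compute_metrics(predictions, truths, probabilities=None) -> MetricsReport:
    """Contingency counts and the derived rates, in percent.

    ``predictions``/``truths`` are class labels with DR positive;
    ``probabilities`` (the global DR probability) enables the trapezoidal
    ROC AUC.
    """
    preds = list(predictions)
    trs = list(truths)
    if len(preds) == 0 or len(preds) != len(trs):
        raise ValueError("empty or misaligned prediction/truth lists")
    p = np.array([x == POSITIVE for x in preds])
    t = np.array([x == POSITIVE for x in trs])
    TP = int(np.sum(p & t)); TN = int(np.sum(~p & ~t))
    FP = int(np.sum(p & ~t)); FN = int(np.sum(~p & t))
    sens = 100.0 * TP / (TP + FN) if TP + FN else float("nan")
    spec = 100.0 * TN / (TN + FP) if TN + FP else float("nan")
    acc = 100.0 * (TP + TN) / len(preds)
    f1 = 100.0 * 2 * TP / (2 * TP + FP + FN) if 2 * TP + FP + FN else float("nan")
    auc = None
    if probabilities is not None and 0 < t.sum() < t.size:
        auc = 100.0 * float(roc_auc_score(t, np.asarray(probabilities)))
    return MetricsReport(TP=TP, TN=TN, FP=FP, FN=FN, sensitivity=sens,
                         specificity=spec, f1=f1, accuracy=acc, auc=auc)


@dataclass
class LineageAudit:
    """Records which scans each fold's model was fitted on, to assert that
    no test-fold scan ever leaks into training-fold fitting."""

    records: list[dict] = field(default_factory=list)

    def check(self, trained_on: list[str], tested_on: list[str],
              fold: int) -> None:
        overlap = set(trained_on) & set(tested_on)
        if overlap:
            raise RuntimeError(
                f"data leakage in fold {fold}: {sorted(overlap)[:5]} used "
                "for both training and testing")
        self.records.append({"fold": fold, "n_train": len(trained_on),
                             "n_test": len(tested_on)})


def run_experiment(
    features: list[LayerFeatureSet],
    manifest: pd.DataFrame,
    schemes: tuple[str, ...] = ("loso",),
    fusion_config: FusionConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    markers_ablation: bool = False,
) -> dict:
    """Cross-validated evaluation of the full fusion pipeline.

    For every requested scheme, trains the fusion model (scalers, SVM
    stacking, BNNs) on the training folds only and evaluates the held-out
    folds; reports the Table-style metrics per fold and pooled, plus ROC
    points over the pooled global probability.  Deterministic given
    (features, config, seed).
    """
    if len(features) != len(manifest):
        raise ValueError("feature/manifest length mismatch")
    fusion_config = fusion_config or FusionConfig(seed=seed)
    report: dict = {"seed": seed, "schemes": {}}
    subjects = manifest["subject_id"].to_numpy()
    truths = np.array([f.class_label for f in features])

    for scheme_name in schemes:
        scheme = make_folds(manifest, scheme_name, seed=seed)
        fold_ids = np.array([scheme.fold_of(s) for s in subjects])
        audit = LineageAudit()
        preds = np.empty(len(features), dtype=object)
        probs = np.zeros(len(features))
        per_fold = []
        for fold in range(scheme.k):
            te = fold_ids == fold
            tr = ~te
            if not te.any():
                continue
            train_feats = [f for f, m in zip(features, tr) if m]
            test_feats = [f for f, m in zip(features, te) if m]
            model = FusionModel(fusion_config)
            model.fit(train_feats)
            audit.check([f.scan_id for f in train_feats],
                        [f.scan_id for f in test_feats], fold)
            diags = model.predict(test_feats)
            preds[te] = [d.predicted_class for d in diags]
            probs[te] = [d.global_probability for d in diags]
            fold_metrics = compute_metrics(preds[te], truths[te])
            per_fold.append({"fold": fold, **{
                k: fold_metrics.as_dict()[k]
                for k in ("TP", "TN", "FP", "FN", "sensitivity",
                          "specificity", "f1", "accuracy")}})
        pooled = compute_metrics(list(preds), list(truths), probs)
        pooled.per_fold = per_fold
        for key in ("sensitivity", "specificity", "f1", "accuracy"):
            vals = np.array([pf[key] for pf in per_fold], dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size:
                pooled.mean_std[key] = (float(vals.mean()),
                                        float(vals.std(ddof=0)))
        fpr, tpr, _ = roc_curve(truths == POSITIVE, probs)
        entry = {"metrics": pooled.as_dict(),
                 "roc": {"fpr": fpr.tolist(), "tpr": tpr.tolist()},
                 "n_folds": scheme.k,
                 "lineage": audit.records}
        report["schemes"][scheme_name] = entry

    if markers_ablation:
        report["single_marker"] = single_marker_metrics(
            features, manifest, scheme="loso", fusion_config=fusion_config,
            seed=seed)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        rows = []
        for name, entry in report["schemes"].items():
            m = entry["metrics"]
            rows.append({"scheme": name, **{k: m[k] for k in
                        ("sensitivity", "specificity", "f1", "accuracy",
                         "auc")}})
        pd.DataFrame(rows).to_csv(out_dir / "metrics.csv", index=False)
    return report


def single_marker_metrics(features, manifest, scheme: str = "loso",
                          fusion_config: FusionConfig | None = None,
                          seed: int = 0) -> dict:
    """Per-marker accuracy: each marker's per-layer SVM probabilities fused
    across layers by a 30-neuron BNN (the marker-ablation protocol)."""
    from .fusion import MARKERS, N_LAYERS
    from .nnet import BNN

    fusion_config = fusion_config or FusionConfig(seed=seed)
    fold_scheme = make_folds(manifest, scheme, seed=seed)
    subjects = manifest["subject_id"].to_numpy()
    fold_ids = np.array([fold_scheme.fold_of(s) for s in subjects])
    truths = np.array([f.class_label for f in features])
    out = {}
    for mi, marker in enumerate(MARKERS):
        preds = np.empty(len(features), dtype=object)
        probs = np.zeros(len(features))
        for fold in range(fold_scheme.k):
            te = fold_ids == fold
            tr = ~te
            train_feats = [f for f, m in zip(features, tr) if m]
            test_feats = [f for f, m in zip(features, te) if m]
            model = FusionModel(fusion_config)
            # train only this marker's SVMs + a 30-neuron across-layer BNN
            y = np.array([1 if f.class_label == POSITIVE else 0
                          for f in train_feats])
            groups = np.array([f.subject_id for f in train_feats])
            from .reflectivity import CIScaler
            from .glcm import GLCMMaxScaler
            from .fusion import CalibratedLinearSVM, _oof_decision_values
            model.ci_scalers = [CIScaler() for _ in range(N_LAYERS)]
            model.glcm_scalers = [GLCMMaxScaler() for _ in range(N_LAYERS)]
            oof = np.zeros((len(train_feats), N_LAYERS))
            for li in range(N_LAYERS):
                X = model._marker_matrix(train_feats, li, marker,
                                         fit_scalers=True)
                X = model._impute(X, (li, marker), fit=True)
                d = _oof_decision_values(X, y, groups,
                                         fusion_config.stacking_folds,
                                         fusion_config.svm_C,
                                         fusion_config.seed)
                clf = CalibratedLinearSVM(C=fusion_config.svm_C,
                                          seed=fusion_config.seed)
                clf.fit(X, y, calib_scores=d, calib_y=y)
                model.svms[(li, marker)] = clf
                oof[:, li] = clf.platt.predict_proba(d.reshape(-1, 1))[:, 1]
            net = BNN(N_LAYERS, 30, 2, params=fusion_config.bnn,
                      seed=fusion_config.seed)
            net.fit(oof, y)
            # evaluate
            test_p = np.zeros((len(test_feats), N_LAYERS))
            for li in range(N_LAYERS):
                X = model._marker_matrix(test_feats, li, marker)
                X = model._impute(X, (li, marker), fit=False)
                test_p[:, li] = model.svms[(li, marker)].predict_proba(X)
            g = net.predict_proba(test_p)[:, 1]
            probs[te] = g
            preds[te] = [POSITIVE if gi >= 0.5 else "normal" for gi in g]
        m = compute_metrics(list(preds), list(truths), probs)
        out[marker] = m.as_dict()
    return out
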