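"""Leave-one-out classification on network features.

Each labeled subject is held out in turn and predicted by a classifier
trained on the remaining subjects' features.  In the default leakage-free
mode every subject's network features are computed under the dual-class
pair models refitted *without that subject* (a jackknife): the predicted
subject never enters the regression fits that define its own network, and
— equally important — the training subjects' features are out-of-sample in
exactly the same way, so the classifier never sees a systematic in-sample
versus out-of-sample feature shift between its training rows and the point
it predicts.  The score is the percentage of subjects classified correctly.

An in-sample mode (``refit_models=False``) that trains the pair models once
on everybody is kept behind a flag for fidelity experiments; it leaks the
held-out subject into the pair fits and should not be used to report
generalization scores.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .dataset import CONTROL, DISEASE, SpectralDataset
from .metrics import FEATURE_COLUMNS, extract_features, feature_table
from .network import reconstruct
from .pairmodel import MIN_CLASS_SIZE, fit_pair_models

CLASSIFIERS = ("svm_linear", "svm_rbf", "naive_bayes", "decision_tree", "mlp")

#: the default feature pair for network-based classification
DEFAULT_FEATURES = ("density", "efficiency")


@dataclass
class ClassificationResult:
    per_subject: pd.DataFrame
    score: float
    config: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.per_subject)


def make_classifier(kind: str, seed: int = 0) -> Pipeline:
    """Classifier pipeline with training-fold standardization.

    Baselines (naive Bayes, decision tree, multilayer perceptron) come from
    scikit-learn with pinned configurations; they are comparison methods,
    not part of the network pipeline itself.
    """
    if kind == "svm_linear":
        clf = SVC(kernel="linear", C=1.0)
    elif kind == "svm_rbf":
        clf = SVC(kernel="rbf", C=1.0, gamma="scale")
    elif kind == "naive_bayes":
        clf = GaussianNB()
    elif kind == "decision_tree":
        clf = DecisionTreeClassifier(random_state=seed)
    elif kind == "mlp":
        clf = MLPClassifier(
            hidden_layer_sizes=(10,), max_iter=2000, random_state=seed
        )
    else:
        raise ValueError(f"unknown classifier {kind!r}; choose from {CLASSIFIERS}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def _check_class_sizes(labels: np.ndarray) -> None:
    for cls in (CONTROL, DISEASE):
        count = int(np.sum(labels == cls))
        if count < MIN_CLASS_SIZE:
            raise ValueError(
                f"{cls} class has {count} labeled subjects; "
                f"at least {MIN_CLASS_SIZE} are required"
            )


def loo_classify(
    data: SpectralDataset,
    *,
    features: tuple[str, ...] = DEFAULT_FEATURES,
    classifier: str = "svm_linear",
    threshold: float = 0.65,
    refit_models: bool = True,
    representation: str = "network",
    symmetrization: str = "mean",
    seed: int = 0,
) -> ClassificationResult:
    """Leave-one-out classification of all labeled subjects.

    ``representation="network"`` classifies on structural network features;
    ``representation="raw"`` feeds the bin intensities directly to the
    classifier (the baseline configuration for robustness comparisons,
    where ``features``/``threshold``/``refit_models`` are ignored).
    """
    if representation not in ("network", "raw"):
        raise ValueError("representation must be 'network' or 'raw'")
    if representation == "network" and not features:
        raise ValueError("features must be non-empty")
    unknown = set(features) - set(FEATURE_COLUMNS)
    if representation == "network" and unknown:
        raise ValueError(f"unknown features {sorted(unknown)}; choose from {FEATURE_COLUMNS}")

    labeled = np.flatnonzero(data.labels != "unlabeled")
    labels = data.labels[labeled]
    _check_class_sizes(labels)

    ids = np.asarray(data.subject_ids, dtype=object)
    if representation == "raw":
        X = data.intensities[labeled]
    elif not refit_models:
        model = fit_pair_models(
            data.intensities[labeled][labels == CONTROL],
            data.intensities[labeled][labels == DISEASE],
            bin_axis=data.bin_axis,
        )
        table = feature_table(
            data, model, threshold=threshold, symmetrization=symmetrization,
            subject_index=labeled,
        )
        X = table[list(features)].to_numpy()
    else:
        # jackknife features: subject k's network is built under the pair
        # models fitted on everyone except k
        rows = []
        for pos, k in enumerate(labeled):
            train = np.delete(labeled, pos)
            train_labels = data.labels[train]
            for cls in (CONTROL, DISEASE):
                if int(np.sum(train_labels == cls)) < MIN_CLASS_SIZE:
                    raise ValueError(
                        f"{cls} class has fewer than {MIN_CLASS_SIZE} subjects "
                        f"after holding out {data.subject_ids[k]!r}"
                    )
            jk_model = fit_pair_models(
                data.intensities[train][train_labels == CONTROL],
                data.intensities[train][train_labels == DISEASE],
                bin_axis=data.bin_axis,
                control_ids=list(ids[train][train_labels == CONTROL]),
                disease_ids=list(ids[train][train_labels == DISEASE]),
            )
            jk_train_ids = set(jk_model.training_ids["control"]) | set(
                jk_model.training_ids["disease"]
            )
            if data.subject_ids[k] in jk_train_ids:
                raise RuntimeError("held-out subject leaked into pair-model fitting")
            net = reconstruct(
                data.intensities[k], jk_model,
                symmetrization=symmetrization, subject_id=data.subject_ids[k],
            )
            rows.append(extract_features(net, threshold).as_dict())
        X = np.array([[row[name] for name in features] for row in rows])

    records = []
    for pos, k in enumerate(labeled):
        train_pos = np.delete(np.arange(len(labeled)), pos)
        clf = make_classifier(classifier, seed=seed)
        clf.fit(X[train_pos], labels[train_pos])
        pred = clf.predict(X[pos : pos + 1])[0]
        rec = {
            "subject_id": data.subject_ids[k],
            "true_label": data.labels[k],
            "predicted_label": pred,
        }
        if representation == "network":
            for name, value in zip(features, X[pos]):
                rec[name] = value
        records.append(rec)

    per_subject = pd.DataFrame(records)
    correct = int((per_subject["true_label"] == per_subject["predicted_label"]).sum())
    score = 100.0 * correct / len(per_subject)
    return ClassificationResult(
        per_subject=per_subject,
        score=score,
        config={
            "features": list(features),
            "classifier": classifier,
            "threshold": threshold,
            "refit_models": refit_models,
            "representation": representation,
            "symmetrization": symmetrization,
            "seed": seed,
        },
    )


def select_features(
    feature_table: pd.DataFrame,
    labels: np.ndarray,
    max_subset: int = 2,
    *,
    classifier: str = "svm_linear",
    seed: int = 0,
) -> list[str]:
    """Exhaustive feature-subset search scored by leave-one-out accuracy.

    Every subset of size 1..max_subset of the table's feature columns is
    scored; ties are broken toward the smaller subset, then lexicographic
    feature names.  (The search is exhaustive by design: the feature space
    here is a handful of network metrics, so brute force is exact and cheap.)
    """
    if feature_table.empty:
        raise ValueError("feature table is empty")
    candidates = sorted(
        c for c in feature_table.columns if c not in ("subject_id", "label", "threshold")
    )
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate features")
    labels = np.asarray(labels, dtype=object)
    best: tuple[int, int, tuple[str, ...]] | None = None
    best_subset: list[str] | None = None
    for size in range(1, max_subset + 1):
        for subset in itertools.combinations(candidates, size):
            X = feature_table[list(subset)].to_numpy()
            correct = 0
            for i in range(len(X)):
                train = np.delete(np.arange(len(X)), i)
                clf = make_classifier(classifier, seed=seed)
                clf.fit(X[train], labels[train])
                if clf.predict(X[i : i + 1])[0] == labels[i]:
                    correct += 1
            key = (-correct, size, subset)
            if best is None or key < best:
                best = key
                best_subset = list(subset)
    return best_subset
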