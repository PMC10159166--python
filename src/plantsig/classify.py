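"""Registry of the ten benchmarked classifier configurations.

Ten scikit-learn configurations from eight algorithm families are
benchmarked: AdaBoost, decision tree, Gaussian naive Bayes, k-NN, MLP,
QDA, random forest (entropy and gini), and SVM (linear and RBF
kernels). Hyperparameters are pinned to the benchmarked settings even
where unusual (AdaBoost learning_rate = 50; gamma set but inert for the
linear-kernel SVM) so results are comparable across runs; overrides are
accepted per spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

#: The ten benchmarked configurations, keyed by registry name.
REGISTRY_DEFAULTS: dict[str, dict] = {
    "adaboost": dict(n_estimators=600, learning_rate=50.0, base_max_depth=5),
    "decision_tree": dict(criterion="gini", splitter="best", max_depth=None,
                          min_samples_split=2, min_samples_leaf=1),
    "gnb": dict(var_smoothing=1e-9),
    "knn": dict(n_neighbors=5, weights="uniform", algorithm="auto",
                leaf_size=30, p=2),
    "mlp": dict(hidden_layer_sizes=(100,), activation="relu", solver="adam",
                alpha=2.0, batch_size="auto"),
    "qda": dict(reg_param=0.0, store_covariance=False, tol=1e-4),
    "rf_entropy": dict(n_estimators=100, criterion="entropy", max_depth=5,
                       min_samples_split=2, class_weight="balanced"),
    "rf_gini": dict(n_estimators=100, criterion="gini", max_depth=5,
                    min_samples_split=2, class_weight=None),
    "svm_linear": dict(C=1.0, kernel="linear", degree=3, gamma=1.5),
    "svm_rbf": dict(C=1.0, kernel="rbf", degree=3, gamma=1.5),
}

CLASSIFIER_NAMES = tuple(sorted(REGISTRY_DEFAULTS))


@dataclass(frozen=True)
class ClassifierSpec:
    """One named classifier configuration with an optional seed.

    ``params`` overrides entries of the registry defaults; the merged
    hyperparameter map is immutable after construction.
    """

    name: str
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.name not in REGISTRY_DEFAULTS:
            raise ValueError(
                f"unknown classifier {self.name!r}; "
                f"valid names: {', '.join(CLASSIFIER_NAMES)}"
            )

    def hyperparameters(self) -> dict:
        merged = dict(REGISTRY_DEFAULTS[self.name])
        merged.update(self.params)
        return merged

    def with_seed(self, seed: int) -> "ClassifierSpec":
        return ClassifierSpec(self.name, dict(self.params), seed)


def make_classifier(spec: ClassifierSpec):
    """Instantiate the scikit-learn estimator for a spec.

    Stochastic models receive ``spec.seed`` as random_state, so two fits
    with the same seed and data give identical predictions.
    """
    p = spec.hyperparameters()
    seed = spec.seed
    name = spec.name
    if name == "adaboost":
        base = DecisionTreeClassifier(max_depth=p["base_max_depth"],
                                      random_state=seed)
        return AdaBoostClassifier(estimator=base,
                                  n_estimators=p["n_estimators"],
                                  learning_rate=p["learning_rate"],
                                  random_state=seed)
    if name == "decision_tree":
        return DecisionTreeClassifier(criterion=p["criterion"],
                                      splitter=p["splitter"],
                                      max_depth=p["max_depth"],
                                      min_samples_split=p["min_samples_split"],
                                      min_samples_leaf=p["min_samples_leaf"],
                                      random_state=seed)
    if name == "gnb":
        return GaussianNB(var_smoothing=p["var_smoothing"])
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=p["n_neighbors"],
                                    weights=p["weights"],
                                    algorithm=p["algorithm"],
                                    leaf_size=p["leaf_size"], p=p["p"])
    if name == "mlp":
        return MLPClassifier(hidden_layer_sizes=p["hidden_layer_sizes"],
                             activation=p["activation"], solver=p["solver"],
                             alpha=p["alpha"], batch_size=p["batch_size"],
                             random_state=seed)
    if name == "qda":
        return QuadraticDiscriminantAnalysis(reg_param=p["reg_param"],
                                             store_covariance=p["store_covariance"],
                                             tol=p["tol"])
    if name in ("rf_entropy", "rf_gini"):
        return RandomForestClassifier(n_estimators=p["n_estimators"],
                                      criterion=p["criterion"],
                                      max_depth=p["max_depth"],
                                      min_samples_split=p["min_samples_split"],
                                      class_weight=p["class_weight"],
                                      random_state=seed)
    if name in ("svm_linear", "svm_rbf"):
        return SVC(C=p["C"], kernel=p["kernel"], degree=p["degree"],
                   gamma=p["gamma"], decision_function_shape="ovr",
                   random_state=seed)
    raise AssertionError("unreachable")  # guarded by ClassifierSpec


class _ConstantClassifier:
    """Degenerate fallback when training data holds a single class."""

    def __init__(self, label):
        self.label = label

    def predict(self, x):
        return np.full(len(x), self.label)


def fit_predict(spec: ClassifierSpec, train: tuple[np.ndarray, np.ndarray],
                test: np.ndarray) -> np.ndarray:
    """Fit the spec's model on (X, y) and predict labels for the test rows."""
    x_train, y_train = np.asarray(train[0], float), np.asarray(train[1])
    x_test = np.asarray(test, float)
    if x_train.shape[1] != x_test.shape[1]:
        raise ValueError("train and test feature dimensions differ")
    classes = np.unique(y_train)
    if classes.size < 2:
        return _ConstantClassifier(classes[0]).predict(x_test)
    model = make_classifier(spec)
    model.fit(x_train, y_train)
    return np.asarray(model.predict(x_test))


def confusion(true: np.ndarray, pred: np.ndarray, n_class: int = 3) -> np.ndarray:
    """Count matrix: entry (i, j) = true class i predicted as class j."""
    true = np.asarray(true, int)
    pred = np.asarray(pred, int)
    if true.shape != pred.shape:
        raise ValueError("label vectors differ in length")
    if true.size and (true.min() < 0 or true.max() >= n_class
                      or pred.min() < 0 or pred.max() >= n_class):
        raise ValueError(f"labels must lie in 0..{n_class - 1}")
    c = np.zeros((n_class, n_class), int)
    np.add.at(c, (true, pred), 1)
    return c
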