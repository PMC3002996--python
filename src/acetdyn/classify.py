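"""Balanced repeated cross-validation of profile-based expression prediction.

How well do 14-bin acetylation-change profiles predict the direction of a
gene's expression change? Four binary problems probe this:

    i    up vs down
    ii   down vs stable
    iii  up vs stable
    iv   differential (up or down) vs stable

Because only ~5% of genes are differential, raw accuracy is dominated by the
majority class (a constant "unchanged" predictor already reaches ~95%). The
harness therefore subsamples the majority class to the minority-class size
(20 balanced resamples by default, chance level 50%) and reports the
stratified 10-fold CV accuracy per resample for every classifier in a
16+-entry registry spanning SVMs, discriminant analysis, trees and
ensembles, k-NN, naive Bayes, a small neural network and logistic
regression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import BaggingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

PROBLEMS = {
    "i": ("up", "down"),
    "ii": ("down", "stable"),
    "iii": ("up", "stable"),
    "iv": ("differential", "stable"),
}


@dataclass
class LabeledDataset:
    """Aligned feature matrix and labels for one day's change profiles."""

    X: np.ndarray                 # genes x 14
    y: np.ndarray                 # {up, down, stable} or binary labels
    genes: np.ndarray
    day: int
    provenance: str = "truth"

    def subset(self, mask: np.ndarray, y: np.ndarray | None = None) -> "LabeledDataset":
        return LabeledDataset(X=self.X[mask], y=self.y[mask] if y is None else y,
                              genes=self.genes[mask], day=self.day,
                              provenance=self.provenance)


@dataclass
class CvReport:
    """accuracies[(problem, classifier)] -> vector of per-resample CV accuracies."""

    accuracies: dict[tuple[str, str], np.ndarray]
    n_resamples: int
    folds: int
    seed: int

    def summary(self) -> pd.DataFrame:
        rows = []
        for (problem, clf), acc in self.accuracies.items():
            q1, med, q3 = np.percentile(acc, [25, 50, 75])
            rows.append((problem, clf, med, q3 - q1, acc.mean(), acc.std()))
        return pd.DataFrame(rows, columns=["problem", "classifier", "median",
                                           "iqr", "mean", "sd"])

    def long_frame(self) -> pd.DataFrame:
        rows = [
            (problem, clf, i, a)
            for (problem, clf), acc in self.accuracies.items()
            for i, a in enumerate(acc)
        ]
        return pd.DataFrame(rows, columns=["problem", "classifier", "resample",
                                           "accuracy"])


class DiagonalLinearDiscriminant(BaseEstimator, ClassifierMixin):
    """Gaussian discriminant with one shared *diagonal* covariance matrix.

    Class scores are linear in x: s_c(x) = x . (mu_c / v) - mu_c^2/(2v)
    + log prior, with v the pooled per-feature variance.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.means_ = np.stack([X[y == c].mean(axis=0) for c in self.classes_])
        resid = X - self.means_[np.searchsorted(self.classes_, y)]
        self.var_ = resid.var(axis=0) + 1e-9
        self.log_prior_ = np.log(
            np.array([(y == c).mean() for c in self.classes_])
        )
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        w = self.means_ / self.var_
        b = -0.5 * (self.means_ ** 2 / self.var_).sum(axis=1) + self.log_prior_
        scores = X @ w.T + b
        return self.classes_[np.argmax(scores, axis=1)]


def classifier_registry() -> dict[str, Callable[[int], BaseEstimator]]:
    """Registry of classifier factories, id -> factory(seed) -> estimator.

    Default hyperparameters (documented here, not tuned): SVMs use C=1 with
    standardized inputs; trees/forests use 100 estimators where aggregated;
    the neural network has one hidden layer of 8 units; k-NN uses Euclidean
    distance on standardized inputs.
    """

    def scaled(est):
        return make_pipeline(StandardScaler(), est)

    reg: dict[str, Callable[[int], BaseEstimator]] = {
        "svm_linear": lambda s: scaled(SVC(kernel="linear", C=1.0)),
        "svm_rbf": lambda s: scaled(SVC(kernel="rbf", C=1.0, gamma="scale")),
        "svm_poly2": lambda s: scaled(SVC(kernel="poly", degree=2, C=1.0, gamma="scale")),
        "svm_poly3": lambda s: scaled(SVC(kernel="poly", degree=3, C=1.0, gamma="scale")),
        "lda": lambda s: LinearDiscriminantAnalysis(),
        "lda_shrinkage": lambda s: LinearDiscriminantAnalysis(solver="lsqr",
                                                              shrinkage="auto"),
        "qda": lambda s: QuadraticDiscriminantAnalysis(reg_param=1e-3),
        "diag_lda": lambda s: DiagonalLinearDiscriminant(),
        "tree": lambda s: DecisionTreeClassifier(random_state=s),
        "bagged_trees": lambda s: BaggingClassifier(
            DecisionTreeClassifier(), n_estimators=100, random_state=s),
        "random_forest": lambda s: RandomForestClassifier(
            n_estimators=100, random_state=s),
        "knn_1": lambda s: scaled(KNeighborsClassifier(n_neighbors=1)),
        "knn_5": lambda s: scaled(KNeighborsClassifier(n_neighbors=5)),
        "knn_10": lambda s: scaled(KNeighborsClassifier(n_neighbors=10)),
        "knn_15": lambda s: scaled(KNeighborsClassifier(n_neighbors=15)),
        "naive_bayes": lambda s: GaussianNB(),
        "neural_net": lambda s: scaled(MLPClassifier(
            hidden_layer_sizes=(8,), max_iter=500, random_state=s)),
        "logistic": lambda s: scaled(LogisticRegression(max_iter=1000)),
    }
    return reg


def dataset_from_changes(changes, truth: pd.Series, day: int,
                         provenance: str = "truth") -> LabeledDataset:
    """Labelled change-profile dataset for one day from association-stage
    change matrices and per-gene labels."""
    delta = changes.delta_profiles[day]
    genes = delta.index.to_numpy()
    y = truth.reindex(genes).to_numpy()
    if pd.isna(y).any():
        keep = ~pd.isna(y)
        genes, y, X = genes[keep], y[keep], delta.to_numpy()[keep]
    else:
        X = delta.to_numpy()
    return LabeledDataset(X=X, y=y.astype(str), genes=genes, day=day,
                          provenance=provenance)


def differential_labels(expr_table: pd.DataFrame, day: int,
                        q_cutoff: float = 0.05, prior_df: float = 4.0) -> pd.Series:
    """Moderated-t differential call of day-``day`` expression versus day 0.

    Per-gene two-sample t between the day's replicates and day 0's, with the
    residual variance shrunk toward the mean gene variance (prior_df pseudo
    degrees of freedom) and BH control at ``q_cutoff``; the sign of the
    change gives up/down, everything else is stable.
    """
    wide = expr_table.pivot_table(index="gene_id", columns=["day", "replicate"],
                                  values="expression")
    x0 = wide[0].to_numpy()
    xt = wide[day].to_numpy()
    n0, nt = x0.shape[1], xt.shape[1]
    diff = xt.mean(axis=1) - x0.mean(axis=1)
    s2 = (x0.var(axis=1, ddof=1) * (n0 - 1) + xt.var(axis=1, ddof=1) * (nt - 1)) / (
        n0 + nt - 2)
    df_resid = n0 + nt - 2
    s2_mod = (prior_df * s2.mean() + df_resid * s2) / (prior_df + df_resid)
    t = diff / np.sqrt(s2_mod * (1 / n0 + 1 / nt))
    p = 2 * stats.t.sf(np.abs(t), df=df_resid + prior_df)
    qv = stats.false_discovery_control(p, method="bh")
    labels = np.where(qv <= q_cutoff, np.where(diff > 0, "up", "down"), "stable")
    return pd.Series(labels, index=wide.index, name="label")


def make_problem(dataset: LabeledDataset, problem_id: str) -> LabeledDataset:
    """Restrict and relabel a 3-class dataset to one binary problem."""
    if problem_id not in PROBLEMS:
        raise ValueError(f"unknown problem {problem_id!r}; choose from {list(PROBLEMS)}")
    pos, neg = PROBLEMS[problem_id]
    y = dataset.y.astype(object).copy()
    if problem_id == "iv":
        y[np.isin(y, ["up", "down"])] = "differential"
    mask = np.isin(y, [pos, neg])
    y_bin = y[mask].astype(str)
    for cls in (pos, neg):
        if not np.any(y_bin == cls):
            raise ValueError(f"problem {problem_id}: class {cls!r} is empty")
    return dataset.subset(mask, y=y_bin)


def balanced_resamples(dataset: LabeledDataset, n_resamples: int = 20,
                       seed: int = 0) -> list[LabeledDataset]:
    """Balanced datasets: the full minority class plus an equally sized
    without-replacement sample of the majority class, ``n_resamples`` times.

    If the classes are already equal the resamples are copies of the full
    dataset.
    """
    classes, counts = np.unique(dataset.y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("balanced_resamples expects a binary dataset")
    min_i = int(np.argmin(counts))
    minority = classes[min_i]
    majority = classes[1 - min_i]
    n_min = counts.min()
    min_idx = np.flatnonzero(dataset.y == minority)
    maj_idx = np.flatnonzero(dataset.y == majority)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_resamples):
        if len(maj_idx) == n_min:
            take = np.concatenate([min_idx, maj_idx])
        else:
            take = np.concatenate([
                min_idx, rng.choice(maj_idx, size=n_min, replace=False)
            ])
        take = np.sort(take)
        out.append(dataset.subset(take))
    return out


def run_cv(dataset: LabeledDataset, classifier_id: str, folds: int = 10,
           seed: int = 0,
           registry: dict[str, Callable] | None = None) -> float:
    """Stratified k-fold CV accuracy (pooled over held-out folds), training a
    fresh classifier per fold."""
    registry = registry or classifier_registry()
    if classifier_id not in registry:
        raise ValueError(
            f"unknown classifier {classifier_id!r}; registry has {sorted(registry)}"
        )
    classes, counts = np.unique(dataset.y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"need at least {folds} rows per class, got {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = 0
    for k, (train, test) in enumerate(skf.split(dataset.X, dataset.y)):
        est = registry[classifier_id](seed + k)
        est.fit(dataset.X[train], dataset.y[train])
        correct += int((est.predict(dataset.X[test]) == dataset.y[test]).sum())
    return correct / len(dataset.y)


def full_benchmark(dataset: LabeledDataset, problems=("i", "ii", "iii", "iv"),
                   classifiers: list[str] | None = None, n_resamples: int = 20,
                   folds: int = 10, seed: int = 0) -> CvReport:
    """Problems x classifiers x balanced resamples benchmark.

    Each cell holds ``n_resamples`` CV accuracies; resamples are shared
    across classifiers within a problem so methods see identical data.
    """
    registry = classifier_registry()
    classifiers = list(classifiers or registry)
    unknown = set(classifiers) - set(registry)
    if unknown:
        raise ValueError(f"unknown classifier(s) {sorted(unknown)}")
    accuracies: dict[tuple[str, str], np.ndarray] = {}
    for pi, problem in enumerate(problems):
        binary = make_problem(dataset, problem)
        resamples = balanced_resamples(binary, n_resamples=n_resamples,
                                       seed=seed + 1000 * pi)
        for clf in classifiers:
            acc = np.array([
                run_cv(rs, clf, folds=folds, seed=seed + 17 * i, registry=registry)
                for i, rs in enumerate(resamples)
            ])
            accuracies[(problem, clf)] = acc
    return CvReport(accuracies=accuracies, n_resamples=n_resamples,
                    folds=folds, seed=seed)
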