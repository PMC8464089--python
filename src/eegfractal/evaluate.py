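"""Nested cross-validated classifier evaluation over ranked feature subsets.

Accuracy is estimated with nested stratified ten-fold cross-validation: the
outer loop measures generalization; for every outer training part an inner
stratified ten-fold loop picks the hyperparameter grid point with the best
mean inner accuracy (ties go to the simplest, i.e. first-listed, point).
The chosen model is refit on the whole outer training part with z-score
feature standardization fitted on training data only, and scored on the
held-out fold.  Reported accuracy is the mean of outer-fold accuracies in
percent (pooled-prediction accuracy is available as an option).

`sequential_curve` adds top-ranked features one at a time and records the
accuracy curve together with its optimal point — the smallest number of
features attaining the maximum.  Ranking can be computed once on the full
matrix ("global", mirroring a single published ranking table) or inside
every outer training fold ("foldwise", which is leakage-safe and the mode
to trust for honest validation).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .relieff import FeatureRanking, relieff_rank, top_n

__all__ = [
    "ProblemDefinition",
    "ClassifierSpec",
    "EvaluationCurve",
    "DEFAULT_PROBLEM_NAMES",
    "problem_from_name",
    "default_problems",
    "default_classifiers",
    "nested_cv_accuracy",
    "sequential_curve",
    "run_problem_suite",
]

#: The five standard class groupings for the Bonn five-collection corpus:
#: two 3-class problems and three binary problems.
DEFAULT_PROBLEM_NAMES = ("ABCD/E", "AB/CD/E", "A/D/E", "A/E", "D/E")

N_FOLDS = 10


@dataclass(frozen=True)
class ProblemDefinition:
    """A classification sub-problem: which class tags map to which group."""

    name: str
    label_map: Mapping[str, int]

    def __post_init__(self) -> None:
        groups = set(self.label_map.values())
        if len(groups) < 2:
            raise ValueError(f"problem {self.name!r} needs >= 2 groups")

    @property
    def included_classes(self) -> list[str]:
        return sorted(self.label_map)

    def map_labels(self, labels: Sequence[str]) -> np.ndarray:
        return np.array([self.label_map[t] for t in labels])


def problem_from_name(name: str) -> ProblemDefinition:
    """Parse a grouping like ``'ABCD/E'`` into a problem definition.

    Each ``/``-separated token is one problem class; each character in a
    token is an original class tag.
    """
    groups = name.split("/")
    if len(groups) < 2 or any(not g for g in groups):
        raise ValueError(f"malformed problem name {name!r}")
    label_map: dict[str, int] = {}
    for gi, group in enumerate(groups):
        for tag in group:
            if tag in label_map:
                raise ValueError(f"class tag {tag!r} appears twice in {name!r}")
            label_map[tag] = gi
    return ProblemDefinition(name=name, label_map=label_map)


def default_problems() -> list[ProblemDefinition]:
    return [problem_from_name(n) for n in DEFAULT_PROBLEM_NAMES]


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family plus its hyperparameter grid (simplest first).

    kinds: ``mlp`` (single hidden layer, tanh activation), ``svm_linear``,
    ``svm_rbf``.  Grid entries are dicts of estimator keyword arguments.
    """

    kind: str
    grid: tuple[Mapping[str, float], ...]

    def __post_init__(self) -> None:
        if self.kind not in ("mlp", "svm_linear", "svm_rbf"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if not self.grid:
            raise ValueError("hyperparameter grid must be non-empty")

    def build(self, params: Mapping[str, float], seed: int):
        if self.kind == "mlp":
            return MLPClassifier(
                hidden_layer_sizes=(int(params["hidden"]),),
                activation="tanh",
                max_iter=400,
                random_state=seed,
            )
        if self.kind == "svm_linear":
            return SVC(kernel="linear", C=params["C"])
        return SVC(kernel="rbf", C=params["C"], gamma=params["gamma"])


def default_classifiers(kinds: Sequence[str] = ("mlp", "svm_linear", "svm_rbf")) -> list[ClassifierSpec]:
    """Standard log-spaced grids spanning under- to over-fitting."""
    specs = {
        "mlp": ClassifierSpec(
            "mlp", tuple({"hidden": h} for h in (2, 5, 10, 20, 40))
        ),
        "svm_linear": ClassifierSpec(
            "svm_linear", tuple({"C": c} for c in (0.01, 0.1, 1.0, 10.0, 100.0))
        ),
        "svm_rbf": ClassifierSpec(
            "svm_rbf",
            tuple(
                {"C": c, "gamma": g}
                for c in (0.01, 0.1, 1.0, 10.0, 100.0)
                for g in (1e-3, 1e-2, 1e-1, 1.0, 10.0)
            ),
        ),
    }
    return [specs[k] for k in kinds]


@dataclass
class EvaluationCurve:
    """Accuracy (%) as a function of the number of top-ranked features."""

    problem: str
    classifier: str
    accuracies: list[float]  # index i -> top-(i+1) features
    all_features_accuracy: float = float("nan")

    @property
    def optimal_point(self) -> tuple[int, float]:
        """(n*, accuracy*): smallest n attaining the curve maximum."""
        best = max(self.accuracies)
        n_star = self.accuracies.index(best) + 1
        return n_star, best


# ---------------------------------------------------------------------------


def _check_folds(y: np.ndarray, n_folds: int) -> None:
    counts = np.bincount(y)
    small = counts[counts > 0].min() if counts.any() else 0
    if small < n_folds:
        raise ValueError(
            f"smallest problem class has {small} members; "
            f"{n_folds}-fold CV needs at least {n_folds} per class"
        )


def _fit_score(spec, params, seed, x_tr, y_tr, x_te, y_te) -> float:
    scaler = StandardScaler().fit(x_tr)
    clf = spec.build(params, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(scaler.transform(x_tr), y_tr)
        return float(clf.score(scaler.transform(x_te), y_te))


def _select_params(spec, x_tr, y_tr, seed) -> Mapping[str, float]:
    """Inner stratified CV over the grid; ties go to the first grid point."""
    if len(spec.grid) == 1:
        return spec.grid[0]
    counts = np.bincount(y_tr)
    inner_splits = min(N_FOLDS, int(counts[counts > 0].min()))
    inner = StratifiedKFold(n_splits=inner_splits, shuffle=True, random_state=seed)
    folds = list(inner.split(x_tr, y_tr))
    best_params, best_score = spec.grid[0], -1.0
    for params in spec.grid:
        scores = [
            _fit_score(spec, params, seed, x_tr[tr], y_tr[tr], x_tr[te], y_tr[te])
            for tr, te in folds
        ]
        mean = float(np.mean(scores))
        if mean > best_score + 1e-12:
            best_params, best_score = params, mean
    return best_params


def nested_cv_accuracy(
    matrix: pd.DataFrame,
    labels: Sequence[str],
    problem: ProblemDefinition,
    spec: ClassifierSpec,
    feature_subset: Sequence[str] | None = None,
    seed: int = 0,
    pooled: bool = False,
) -> float:
    """Nested stratified ten-fold CV accuracy (%) for one feature subset.

    Rows whose label is not in the problem's class map are dropped.  Feature
    standardization and hyperparameter selection see only training folds.
    Deterministic for a fixed seed.
    """
    names = list(matrix.columns) if feature_subset is None else list(feature_subset)
    missing = [f for f in names if f not in matrix.columns]
    if missing:
        raise ValueError(f"unknown features in subset: {missing}")
    keep = np.array([t in problem.label_map for t in labels])
    x = matrix.loc[keep, names].to_numpy(dtype=float)
    y = problem.map_labels(np.asarray(labels)[keep])
    _check_folds(y, N_FOLDS)

    outer = StratifiedKFold(n_splits=N_FOLDS, shuffle=True, random_state=seed)
    fold_acc, n_correct, n_total = [], 0, 0
    for tr, te in outer.split(x, y):
        params = _select_params(spec, x[tr], y[tr], seed + 1)
        acc = _fit_score(spec, params, seed, x[tr], y[tr], x[te], y[te])
        fold_acc.append(acc)
        n_correct += acc * te.size
        n_total += te.size
    if pooled:
        return 100.0 * n_correct / n_total
    return 100.0 * float(np.mean(fold_acc))


def sequential_curve(
    matrix: pd.DataFrame,
    labels: Sequence[str],
    problem: ProblemDefinition,
    spec: ClassifierSpec,
    ranking: FeatureRanking | None = None,
    ranking_mode: str = "global",
    max_features: int | None = None,
    seed: int = 0,
    relieff_k: int = 10,
) -> EvaluationCurve:
    """Accuracy versus number of top-ranked features, plus the optimum.

    In ``global`` mode the supplied ranking (or one computed on the whole
    problem matrix) orders features for every fold.  In ``foldwise`` mode
    the ranking is recomputed from each outer training part, so the feature
    order never sees held-out data.
    """
    if ranking_mode not in ("global", "foldwise"):
        raise ValueError(f"ranking_mode must be 'global' or 'foldwise', got {ranking_mode!r}")
    keep = np.array([t in problem.label_map for t in labels])
    sub = matrix.loc[keep]
    y = problem.map_labels(np.asarray(labels)[keep])
    _check_folds(y, N_FOLDS)
    n_feat = sub.shape[1]
    n_max = n_feat if max_features is None else min(max_features, n_feat)

    accs: list[float]
    if ranking_mode == "global":
        if ranking is None:
            ranking = relieff_rank(sub, y, k_neighbors=relieff_k)
        if set(ranking.order) != set(matrix.columns):
            raise ValueError("ranking must cover exactly the matrix features")
        accs = [
            nested_cv_accuracy(matrix, labels, problem, spec, top_n(ranking, n), seed=seed)
            for n in range(1, n_max + 1)
        ]
        all_acc = nested_cv_accuracy(matrix, labels, problem, spec, None, seed=seed)
    else:
        x = sub.to_numpy(dtype=float)
        outer = StratifiedKFold(n_splits=N_FOLDS, shuffle=True, random_state=seed)
        per_fold = np.zeros((N_FOLDS, n_max))
        all_fold = np.zeros(N_FOLDS)
        cols = list(sub.columns)
        for fi, (tr, te) in enumerate(outer.split(x, y)):
            fold_rank = relieff_rank(sub.iloc[tr], y[tr], k_neighbors=relieff_k)
            for n in range(1, n_max + 1):
                idx = [cols.index(f) for f in top_n(fold_rank, n)]
                params = _select_params(spec, x[tr][:, idx], y[tr], seed + 1)
                per_fold[fi, n - 1] = _fit_score(
                    spec, params, seed, x[tr][:, idx], y[tr], x[te][:, idx], y[te]
                )
            params = _select_params(spec, x[tr], y[tr], seed + 1)
            all_fold[fi] = _fit_score(spec, params, seed, x[tr], y[tr], x[te], y[te])
        accs = list(100.0 * per_fold.mean(axis=0))
        all_acc = 100.0 * float(all_fold.mean())

    return EvaluationCurve(
        problem=problem.name,
        classifier=spec.kind,
        accuracies=[float(a) for a in accs],
        all_features_accuracy=float(all_acc),
    )


def run_problem_suite(
    matrix: pd.DataFrame,
    labels: Sequence[str],
    problems: Sequence[ProblemDefinition] | None = None,
    specs: Sequence[ClassifierSpec] | None = None,
    ranking_mode: str = "global",
    max_features: int | None = None,
    seed: int = 0,
    relieff_k: int = 10,
) -> dict:
    """Evaluate every (problem, classifier) pair; report curves and top features.

    Returns a dict with per-problem rankings (top five highlighted, in the
    layout of a published feature table) and per-pair evaluation curves
    with optimal points and with/without-selection accuracies.
    """
    problems = list(problems) if problems is not None else default_problems()
    specs = list(specs) if specs is not None else default_classifiers()
    labels = np.asarray(labels)
    report: dict = {"problems": {}, "curves": []}
    for problem in problems:
        keep = np.array([t in problem.label_map for t in labels])
        sub = matrix.loc[keep]
        y = problem.map_labels(labels[keep])
        ranking = relieff_rank(sub, y, k_neighbors=relieff_k)
        entry = {
            "ranking": ranking,
            "top5": top_n(ranking, min(5, len(ranking.order))),
            "curves": {},
        }
        for spec in specs:
            curve = sequential_curve(
                matrix,
                labels,
                problem,
                spec,
                ranking=ranking if ranking_mode == "global" else None,
                ranking_mode=ranking_mode,
                max_features=max_features,
                seed=seed,
                relieff_k=relieff_k,
            )
            n_star, acc_star = curve.optimal_point
            entry["curves"][spec.kind] = curve
            report["curves"].append(
                {
                    "problem": problem.name,
                    "classifier": spec.kind,
                    "optimal_n": n_star,
                    "optimal_accuracy": acc_star,
                    "all_features_accuracy": curve.all_features_accuracy,
                }
            )
        report["problems"][problem.name] = entry
    return report
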