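"""Edge-feature classification of brain functional networks.

Implements the evaluation protocol used to compare BFNs of different
orders: the upper-triangle edge weights are the features, a two-sample
t-test filters edges on the training folds, a linear SVM (C = 1) with
Platt-style sigmoid calibration produces class probabilities, and
performance is scored by subject-level k-fold cross-validation (all scans
of one subject stay on the same side of the train/test boundary).  A
low-order and a higher-order network can be fused late, as the convex
combination ``lambda * O1 + (1 - lambda) * O2`` of the two classifiers'
probabilistic outputs, with lambda picked by an inner CV on the training
folds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .bfn import AdjacencyMatrix, ValidationError

__all__ = [
    "OrderKey",
    "ScanRecord",
    "LabeledDataset",
    "FoldSplit",
    "MetricsReport",
    "FusionResult",
    "vectorize_edges",
    "ttest_select",
    "subject_level_folds",
    "train_probabilistic_classifier",
    "PlattCalibratedLinearSVM",
    "evaluate_metrics",
    "fuse_probabilities",
    "select_lambda",
    "run_experiment",
    "EdgeClassificationExperiment",
    "ExperimentResults",
    "DEFAULT_LAMBDA_GRID",
    "DEFAULT_P_GRID",
]

OrderKey = Union[int, str]  # an integer order or "conv"

#: Lambda grid for late fusion.
DEFAULT_LAMBDA_GRID = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)

#: Default p-value grid for t-test edge selection.
DEFAULT_P_GRID = (0.05, 0.01, 0.005, 0.001)


@dataclass(frozen=True)
class ScanRecord:
    """One scan's BFN matrices (keyed by order) plus subject/label."""

    matrices: dict
    subject_id: str
    label: str

    def __post_init__(self):
        if not self.subject_id:
            raise ValidationError("every scan needs a subject_id")
        for key, mat in self.matrices.items():
            if not isinstance(mat, AdjacencyMatrix):
                raise ValidationError(f"matrix at order {key!r} is not an AdjacencyMatrix")


@dataclass(frozen=True)
class LabeledDataset:
    """Scans with subject IDs and binary labels.

    A subject may own several scans; fold splitting is done at the subject
    level.  ``positive_class_name`` fixes which label counts as positive
    for sensitivity/specificity.
    """

    scans: tuple
    positive_class_name: str = "positive"

    def __post_init__(self):
        scans = tuple(self.scans)
        if not scans:
            raise ValidationError("empty dataset")
        labels = {s.label for s in scans}
        if len(labels) != 2:
            raise ValidationError(f"need exactly 2 classes, got {sorted(labels)}")
        if self.positive_class_name not in labels:
            raise ValidationError(
                f"positive class {self.positive_class_name!r} not among labels {sorted(labels)}"
            )
        object.__setattr__(self, "scans", scans)

    def __len__(self) -> int:
        return len(self.scans)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.scans]

    def labels(self) -> np.ndarray:
        """Binary label vector: 1 for the positive class."""
        return np.array(
            [1 if s.label == self.positive_class_name else 0 for s in self.scans],
            dtype=int,
        )

    def features(self, order: OrderKey) -> np.ndarray:
        """Scans x edges matrix of vectorized edge weights at ``order``."""
        rows = []
        for s in self.scans:
            if order not in s.matrices:
                raise ValidationError(
                    f"scan of subject {s.subject_id} has no matrix at order {order!r}"
                )
            rows.append(vectorize_edges(s.matrices[order]))
        return np.vstack(rows)

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset(
            scans=tuple(self.scans[i] for i in indices),
            positive_class_name=self.positive_class_name,
        )

    def subject_majority_labels(self) -> dict:
        """Majority scan label per subject (ties go to the positive class)."""
        by_subject: dict[str, list[str]] = {}
        for s in self.scans:
            by_subject.setdefault(s.subject_id, []).append(s.label)
        out = {}
        for subj, labs in by_subject.items():
            n_pos = sum(1 for l in labs if l == self.positive_class_name)
            out[subj] = (
                self.positive_class_name
                if 2 * n_pos >= len(labs)
                else next(l for l in labs if l != self.positive_class_name)
            )
        return out


@dataclass(frozen=True)
class FoldSplit:
    """Subject -> fold assignment for subject-level cross-validation."""

    assignments: dict
    k: int

    def __post_init__(self):
        folds = set(self.assignments.values())
        if not folds <= set(range(self.k)):
            raise ValidationError("fold indices out of range")
        sizes = self.fold_sizes()
        if max(sizes) - min(sizes) > 1:
            raise ValidationError(f"fold sizes (in subjects) differ by more than 1: {sizes}")

    def fold_sizes(self) -> list[int]:
        sizes = [0] * self.k
        for f in self.assignments.values():
            sizes[f] += 1
        return sizes

    def test_indices(self, ds: LabeledDataset, fold: int) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(ds.scans) if self.assignments[s.subject_id] == fold],
            dtype=int,
        )

    def train_indices(self, ds: LabeledDataset, fold: int) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(ds.scans) if self.assignments[s.subject_id] != fold],
            dtype=int,
        )


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts and ACC/SEN/SPE, recomputable from the counts.

    ACC = (TP+TN) / (TP+TN+FP+FN), SEN = TP / (TP+FN), SPE = TN / (TN+FP);
    a zero denominator yields NaN and the metric's name in ``undefined``.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    acc: float
    sen: float
    spe: float
    undefined: tuple[str, ...] = ()
    per_fold: Optional[tuple] = None
    p_threshold: Optional[float] = None
    order: Optional[OrderKey] = None
    n_features_selected: Optional[tuple[int, ...]] = None

    def to_dict(self) -> dict:
        d = {
            "TP": self.tp,
            "TN": self.tn,
            "FP": self.fp,
            "FN": self.fn,
            "ACC": self.acc,
            "SEN": self.sen,
            "SPE": self.spe,
            "undefined": list(self.undefined),
            "p_threshold": self.p_threshold,
            "order": self.order,
            "n_features_selected": (
                list(self.n_features_selected) if self.n_features_selected is not None else None
            ),
        }
        if self.per_fold is not None:
            d["per_fold"] = [m.to_dict() for m in self.per_fold]
        return d


@dataclass(frozen=True)
class FusionResult:
    """Late-fusion outcome: per-fold lambda, fused per-scan probabilities
    (aligned with the dataset's scan order), and pooled metrics."""

    lambda_selected: tuple[float, ...]
    fused_probabilities: np.ndarray
    metrics: MetricsReport

    def to_dict(self) -> dict:
        return {
            "lambda_selected": list(self.lambda_selected),
            "fused_probabilities": np.asarray(self.fused_probabilities).tolist(),
            "metrics": self.metrics.to_dict(),
        }


def vectorize_edges(R: AdjacencyMatrix) -> np.ndarray:
    """Strict upper triangle in row-major order (1,2),(1,3),...,(N-1,N)."""
    n = R.n_rois
    iu = np.triu_indices(n, k=1)
    return R.values[iu]


def ttest_select(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    p_threshold: float,
    equal_var: bool = True,
) -> np.ndarray:
    """Edge indices whose two-sample t-test p-value is below ``p_threshold``.

    Pooled-variance t-test by default (``equal_var=False`` gives Welch).
    Edges that are constant within both groups have an undefined statistic
    and are never selected.  An empty selection is allowed but flagged
    with a warning.
    """
    if not 0 < p_threshold < 1:
        raise ValidationError(f"p_threshold must be in (0, 1), got {p_threshold}")
    y = np.asarray(train_labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValidationError("t-test selection needs both classes in the training labels")
    a = train_features[y == classes[0]]
    b = train_features[y == classes[1]]
    with np.errstate(divide="ignore", invalid="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            _, pvals = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    selected = np.flatnonzero(np.nan_to_num(pvals, nan=1.0) < p_threshold)
    if selected.size == 0:
        warnings.warn(
            f"t-test at p < {p_threshold} selected no edges", UserWarning, stacklevel=2
        )
    return selected


def subject_level_folds(ds: LabeledDataset, k: int = 5, seed: int = 0) -> FoldSplit:
    """Deal subjects into ``k`` folds of near-equal size.

    Subjects are stratified by their majority scan label (so folds keep
    roughly the class proportions), shuffled within strata by ``seed``,
    and dealt round-robin; all scans of a subject share one fold and fold
    sizes in subjects differ by at most one.
    """
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    majority = ds.subject_majority_labels()
    subjects = sorted(majority)
    if len(subjects) < k:
        raise ValidationError(f"{len(subjects)} subjects < {k} folds")
    rng = np.random.default_rng(seed)
    ordered: list[str] = []
    for label in sorted({majority[s] for s in subjects}):
        stratum = [s for s in subjects if majority[s] == label]
        ordered.extend(np.array(stratum, dtype=object)[rng.permutation(len(stratum))])
    assignments = {subj: i % k for i, subj in enumerate(ordered)}
    return FoldSplit(assignments=assignments, k=k)


class PlattCalibratedLinearSVM:
    """Linear max-margin classifier with sigmoid probability calibration.

    Fits an SVM with a linear kernel (regularization parameter ``C``,
    default 1) and then a one-dimensional logistic regression on the
    training decision values, mapping margins to probabilities of the
    positive (larger) class.  If the feature matrix has zero columns —
    e.g. the edge selection came up empty — the classifier falls back to
    the training majority-class probability, with a warning.
    """

    def __init__(self, C: float = 1.0):
        self.C = float(C)
        self._svc: Optional[SVC] = None
        self._platt: Optional[LogisticRegression] = None
        self._fallback_prob: Optional[float] = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PlattCalibratedLinearSVM":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if np.unique(y).size != 2:
            raise ValidationError("classifier training needs both classes")
        if X.shape[1] == 0:
            warnings.warn(
                "empty feature set; falling back to majority-class probability",
                UserWarning,
                stacklevel=2,
            )
            self._fallback_prob = float(np.mean(y))
            return self
        self._svc = SVC(kernel="linear", C=self.C)
        self._svc.fit(X, y)
        margins = self._svc.decision_function(X).reshape(-1, 1)
        self._platt = LogisticRegression(C=1.0, solver="lbfgs")
        self._platt.fit(margins, y)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        if self._svc is None:
            return np.zeros(len(X))
        return self._svc.decision_function(np.asarray(X, dtype=float))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability of the positive class per scan."""
        if self._svc is None:
            return np.full(len(X), self._fallback_prob)
        margins = self.decision_function(X).reshape(-1, 1)
        return self._platt.predict_proba(margins)[:, 1]


def train_probabilistic_classifier(
    features: np.ndarray, labels: np.ndarray, C: float = 1.0
) -> PlattCalibratedLinearSVM:
    """Fit the linear SVM + Platt sigmoid on a training feature matrix."""
    return PlattCalibratedLinearSVM(C=C).fit(features, labels)


def evaluate_metrics(
    probabilities: np.ndarray,
    labels: np.ndarray,
    threshold: float = 0.5,
    **report_fields,
) -> MetricsReport:
    """Confusion counts and ACC/SEN/SPE from probabilities at a threshold."""
    probs = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if probs.shape != y.shape:
        raise ValidationError("probabilities and labels must be aligned")
    pred = probs >= threshold
    tp = int(np.sum(pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    undefined = []

    def _ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return math.nan
        return num / den

    acc = _ratio(tp + tn, tp + tn + fp + fn, "ACC")
    sen = _ratio(tp, tp + fn, "SEN")
    spe = _ratio(tn, tn + fp, "SPE")
    return MetricsReport(
        tp=tp, tn=tn, fp=fp, fn=fn, acc=acc, sen=sen, spe=spe,
        undefined=tuple(undefined), **report_fields,
    )


def fuse_probabilities(O1: np.ndarray, O2: np.ndarray, lam: float) -> np.ndarray:
    """Convex late fusion ``lam * O1 + (1 - lam) * O2``."""
    O1 = np.asarray(O1, dtype=float)
    O2 = np.asarray(O2, dtype=float)
    if O1.shape != O2.shape:
        raise ValidationError("fusion inputs must have equal length")
    if not 0.0 <= lam <= 1.0:
        raise ValidationError(f"lambda must be in [0, 1], got {lam}")
    return lam * O1 + (1.0 - lam) * O2


def _fold_probabilities(ds, order, split, fold, p_threshold, C, equal_var, global_sel):
    """Train on the fold's complement, return (test_idx, probs, n_selected,
    selected_indices)."""
    tr = split.train_indices(ds, fold)
    te = split.test_indices(ds, fold)
    F = ds.features(order)
    y = ds.labels()
    if global_sel is not None:
        sel = global_sel
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            sel = ttest_select(F[tr], y[tr], p_threshold, equal_var=equal_var)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        clf = train_probabilistic_classifier(F[tr][:, sel], y[tr], C=C)
    return te, clf.predict_proba(F[te][:, sel]), int(sel.size), sel


def select_lambda(
    train_ds: LabeledDataset,
    order_n: OrderKey,
    p_threshold: float,
    grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    inner_k: int = 5,
    seed: int = 0,
    C: float = 1.0,
    equal_var: bool = True,
) -> float:
    """Pick the fusion weight by an inner subject-level CV on the training set.

    For each inner split the full pipeline runs from scratch (edge
    selection and both classifiers fitted on the inner-training scans
    only); ``O1`` comes from the order-1 network and ``O2`` from
    ``order_n``.  The lambda with the highest mean inner accuracy wins;
    ties go to the value nearest 0.5, then to the smaller value.
    """
    grid = [float(g) for g in grid]
    if not grid or not all(0.0 < g < 1.0 for g in grid):
        raise ValidationError("lambda grid must be nonempty within (0, 1)")
    if inner_k < 2:
        raise ValidationError(f"inner_k must be >= 2, got {inner_k}")
    split = subject_level_folds(train_ds, k=inner_k, seed=seed)
    y = train_ds.labels()
    fold_accs = np.zeros((inner_k, len(grid)))
    for fold in range(inner_k):
        te1, O1, _, _ = _fold_probabilities(
            train_ds, 1, split, fold, p_threshold, C, equal_var, None
        )
        _, O2, _, _ = _fold_probabilities(
            train_ds, order_n, split, fold, p_threshold, C, equal_var, None
        )
        for j, lam in enumerate(grid):
            fused = fuse_probabilities(O1, O2, lam)
            fold_accs[fold, j] = np.mean((fused >= 0.5).astype(int) == y[te1])
    mean_accs = fold_accs.mean(axis=0)
    best = mean_accs.max()
    # tie-break: closest to 0.5, then smaller
    tied = [g for g, a in zip(grid, mean_accs) if a >= best - 1e-12]
    tied.sort(key=lambda g: (abs(g - 0.5), g))
    return tied[0]


def run_experiment(
    ds: LabeledDataset,
    orders: Sequence[OrderKey],
    p_grid: Sequence[float] = DEFAULT_P_GRID,
    mode: str = "single",
    k: int = 5,
    seed: int = 0,
    C: float = 1.0,
    selection_scope: str = "fold",
    equal_var: bool = True,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    inner_k: int = 5,
) -> dict:
    """Outer subject-level k-fold CV over orders and p-thresholds.

    ``mode="single"`` scores each order's network on its own; the result
    maps ``(order, p)`` to a pooled :class:`MetricsReport` (with per-fold
    reports and per-fold selected-feature counts).  ``mode="fusion"``
    fuses each higher order with order 1: within every outer training
    fold, lambda is chosen by an inner subject-level CV, both classifiers
    are then retrained on the whole training fold, and the fused test
    probabilities are pooled; results are keyed ``("<n>&1", p)`` as
    :class:`FusionResult`.  All selection, calibration and lambda tuning
    see only training-fold scans.
    """
    if mode not in ("single", "fusion"):
        raise ValidationError(f"unknown mode {mode!r}")
    if selection_scope not in ("fold", "global"):
        raise ValidationError(f"unknown selection_scope {selection_scope!r}")
    split = subject_level_folds(ds, k=k, seed=seed)
    y = ds.labels()
    results: dict = {}
    work_orders = list(orders)
    if mode == "fusion":
        work_orders = [o for o in work_orders if o != 1]
        if not work_orders:
            raise ValidationError("fusion mode needs at least one order other than 1")
    for p in p_grid:
        global_sel1 = None
        if selection_scope == "global" and mode == "fusion":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                global_sel1 = ttest_select(ds.features(1), y, p, equal_var=equal_var)
        for order in work_orders:
            global_sel = None
            if selection_scope == "global":
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)
                    global_sel = ttest_select(
                        ds.features(order), y, p, equal_var=equal_var
                    )
            pooled = np.full(len(ds), np.nan)
            per_fold = []
            n_selected = []
            lambdas = []
            for fold in range(k):
                if mode == "single":
                    te, probs, nsel, _ = _fold_probabilities(
                        ds, order, split, fold, p, C, equal_var, global_sel
                    )
                else:
                    tr = split.train_indices(ds, fold)
                    te = split.test_indices(ds, fold)
                    train_ds = ds.subset(tr)
                    lam = select_lambda(
                        train_ds, order, p, grid=lambda_grid, inner_k=inner_k,
                        seed=seed + 1000 * (fold + 1), C=C, equal_var=equal_var,
                    )
                    lambdas.append(lam)
                    # retrain both classifiers on the full outer-training fold
                    _, O1, _, _ = _fold_probabilities(
                        ds, 1, split, fold, p, C, equal_var, global_sel1
                    )
                    _, O2, nsel, _ = _fold_probabilities(
                        ds, order, split, fold, p, C, equal_var, global_sel
                    )
                    probs = fuse_probabilities(O1, O2, lam)
                pooled[te] = probs
                n_selected.append(nsel)
                per_fold.append(evaluate_metrics(probs, y[te]))
            report = evaluate_metrics(
                pooled, y,
                per_fold=tuple(per_fold),
                p_threshold=p,
                order=order if mode == "single" else f"{order}&1",
                n_features_selected=tuple(n_selected),
            )
            if mode == "single":
                results[(order, p)] = report
            else:
                results[(f"{order}&1", p)] = FusionResult(
                    lambda_selected=tuple(lambdas),
                    fused_probabilities=pooled,
                    metrics=report,
                )
    return results


class ExperimentResults:
    """Results container for :class:`EdgeClassificationExperiment`."""

    def __init__(self, results: dict, mode: str, k: int, seed: int):
        self.results = results
        self.mode = mode
        self.k = k
        self.seed = seed

    def __getitem__(self, key):
        return self.results[key]

    def metrics(self, order: OrderKey, p: float) -> MetricsReport:
        item = self.results[(order, p)]
        return item.metrics if isinstance(item, FusionResult) else item

    def to_dict(self) -> dict:
        out = {"mode": self.mode, "k": self.k, "seed": self.seed, "results": {}}
        for (order, p), item in self.results.items():
            out["results"][f"order={order},p={p:g}"] = item.to_dict()
        return out

    def summary(self) -> str:
        lines = [
            f"Edge-feature classification ({self.mode} mode, {self.k}-fold "
            f"subject-level CV, seed {self.seed})",
            f"{'order':>8} {'p':>8} {'ACC':>7} {'SEN':>7} {'SPE':>7} {'#feat (mean)':>13}",
        ]
        for (order, p), item in sorted(
            self.results.items(), key=lambda kv: (str(kv[0][0]), kv[0][1])
        ):
            m = item.metrics if isinstance(item, FusionResult) else item
            nf = (
                float(np.mean(m.n_features_selected))
                if m.n_features_selected
                else float("nan")
            )
            lines.append(
                f"{str(order):>8} {p:>8g} {m.acc:>7.3f} {m.sen:>7.3f} "
                f"{m.spe:>7.3f} {nf:>13.1f}"
            )
        return "\n".join(lines)


class EdgeClassificationExperiment:
    """Model-style front end for the CV classification protocol.

    Construct from a :class:`LabeledDataset` whose scans carry matrices at
    the orders of interest; ``fit(seed)`` runs the full cross-validated
    protocol and returns :class:`ExperimentResults`.
    """

    def __init__(
        self,
        dataset: LabeledDataset,
        orders: Sequence[OrderKey] = (1, 2, 3, 4, "conv"),
        p_grid: Sequence[float] = DEFAULT_P_GRID,
        mode: str = "single",
        k: int = 5,
        C: float = 1.0,
        selection_scope: str = "fold",
        equal_var: bool = True,
        lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
        inner_k: int = 5,
    ):
        self.dataset = dataset
        self.orders = list(orders)
        self.p_grid = list(p_grid)
        self.mode = mode
        self.k = k
        self.C = C
        self.selection_scope = selection_scope
        self.equal_var = equal_var
        self.lambda_grid = list(lambda_grid)
        self.inner_k = inner_k

    def fit(self, seed: int = 0) -> ExperimentResults:
        results = run_experiment(
            self.dataset,
            orders=self.orders,
            p_grid=self.p_grid,
            mode=self.mode,
            k=self.k,
            seed=seed,
            C=self.C,
            selection_scope=self.selection_scope,
            equal_var=self.equal_var,
            lambda_grid=self.lambda_grid,
            inner_k=self.inner_k,
        )
        return ExperimentResults(results, mode=self.mode, k=self.k, seed=seed)
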