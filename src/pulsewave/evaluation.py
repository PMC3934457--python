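"""Cross-validated evaluation protocol and error-rate bookkeeping.

The protocol is nested 10-fold cross-validation: for each outer fold
the remaining nine folds form the training set T, which is split once
(stratified, 8/9 vs 1/9) into T1 for fitting and T2 for hyperparameter
tuning; the grid-search winner is refit on all of T and scored on the
held-out fold.  Pooled predictions across folds populate a confusion
matrix from which per-class and total average error rates (AERs) are
computed.

Grid search sweeps (lam, nu) of the TWED metric, the kernel bandwidth
sigma and the SVM regularizer C.  Distance matrices depend only on
(metric, lam, nu), so they are cached at dataset level and shared
across folds, sigma and C — sweeping sigma/C costs only elementwise
exponentials and small SVM fits.

Outer and inner splits are stratified by default (the rare classes have
too few samples for plain random 10-fold splitting to be safe);
``stratify=False`` restores plain random splitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold, StratifiedShuffleSplit

from .core import CLASS_ORDER, LabeledDataset, ValidationError
from .kernels import KernelParams, kernel_from_distance
from .metrics import ElasticParams, pairwise_distance_matrix
from .svm import nn_predict_from_matrix, predict_from_rows, train_multiclass_from_gram

METHODS = ("gtwed-svm", "gerp-svm", "1nn-twed", "1nn-erp", "1nn-ed")


@dataclass(frozen=True)
class ParamGrid:
    """Hyperparameter grids for tuning (defaults: the full published grids)."""

    lam: tuple[float, ...] = (1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 1.0)
    nu: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    sigma: tuple[float, ...] = (1e-2, 1e-1, 1.0, 10.0, 1e2, 1e3, 1e4)
    C: tuple[float, ...] = (1e-3, 1e-2, 1e-1, 1.0, 10.0, 1e2, 1e3, 1e4, 1e5)

    def __post_init__(self) -> None:
        for name in ("lam", "nu", "sigma", "C"):
            vals = getattr(self, name)
            if len(vals) == 0:
                raise ValidationError(f"grid {name} must be non-empty")
            if name != "nu" and any(v <= 0 for v in vals):
                raise ValidationError(f"grid {name} must be positive")
            if name == "nu" and any(v < 0 for v in vals):
                raise ValidationError("grid nu must be >= 0")

    @classmethod
    def compact(cls) -> "ParamGrid":
        """Desk-scale grid: lam fixed at 1e-2, full nu grid, reduced sigma/C."""
        return cls(lam=(1e-2,), sigma=(10.0, 1e2, 1e3), C=(1.0, 1e2, 1e4))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Rows = actual class, columns = predicted class, fixed class order."""

    counts: np.ndarray
    classes: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if counts.shape != (k, k):
            raise ValidationError(f"expected a {k}x{k} matrix, got {counts.shape}")
        if np.any(counts < 0):
            raise ValidationError("confusion counts must be >= 0")
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    @classmethod
    def from_predictions(
        cls,
        actual: Sequence[str],
        predicted: Sequence[str],
        classes: tuple[str, ...] = CLASS_ORDER,
    ) -> "ConfusionMatrix":
        pos = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for a, p in zip(actual, predicted, strict=True):
            counts[pos[a], pos[p]] += 1
        return cls(counts=counts, classes=classes)

    @property
    def trace(self) -> int:
        return int(np.trace(self.counts))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class AerReport:
    """Per-class and total average error rates, in percent."""

    per_class: dict[str, float]
    total: float


def aer_from_confusion(
    cm: ConfusionMatrix, class_totals: Sequence[int] | None = None
) -> AerReport:
    """AERs from a confusion matrix: (row total - diagonal) / row total, percent.

    ``class_totals``, when given, override the row sums (and the grand
    total becomes their sum).  This reproduces published tables whose
    printed rows disagree slightly with the declared class sizes.
    """
    counts = cm.counts
    diag = np.diag(counts).astype(float)
    if class_totals is not None:
        totals = np.asarray(class_totals, dtype=float)
        if totals.shape != (len(cm.classes),) :
            raise ValidationError("one class total per class required")
    else:
        totals = counts.sum(axis=1).astype(float)
    if np.any(totals <= 0):
        zero = cm.classes[int(np.argmax(totals <= 0))]
        raise ValidationError(f"zero sample total for class {zero!r}")
    per_class = {
        c: float(100.0 * (totals[i] - diag[i]) / totals[i])
        for i, c in enumerate(cm.classes)
    }
    grand = float(totals.sum())
    total = float(100.0 * (grand - diag.sum()) / grand)
    return AerReport(per_class=per_class, total=total)


def stratified_kfold(
    dataset: LabeledDataset | Sequence[str],
    k: int = 10,
    seed: int = 0,
    stratify: bool = True,
) -> list[np.ndarray]:
    """Disjoint test-index sets partitioning the dataset (per-class counts +/-1)."""
    labels = (
        dataset.label_strings if isinstance(dataset, LabeledDataset) else list(dataset)
    )
    n = len(labels)
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    if stratify:
        counts: dict[str, int] = {}
        for lab in labels:
            counts[lab] = counts.get(lab, 0) + 1
        small = [c for c, cnt in counts.items() if cnt < k]
        if small:
            raise ValidationError(
                f"classes {small} have fewer than k={k} samples; use a smaller k"
            )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return [test for _, test in splitter.split(np.zeros(n), labels)]
    if n < k:
        raise ValidationError(f"dataset of {n} samples cannot be split into {k} folds")
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros(n))]


class DistanceCache:
    """Dataset-level cache of pairwise distance matrices, keyed by metric params.

    The dynamic programs dominate runtime, and a grid search re-uses each
    (lam, nu) matrix for every (sigma, C) combination, so matrices are
    computed lazily once per key and shared across folds.
    """

    def __init__(self, dataset: LabeledDataset):
        self.xs = [p.to_timeseries() for p in dataset.periods]
        self._store: dict[tuple, np.ndarray] = {}
        self.n_computed = 0

    def get(
        self,
        metric: str,
        params: ElasticParams | None = None,
        gap: float = 0.0,
        p: int = 1,
    ) -> np.ndarray:
        if metric == "twed":
            prm = params if params is not None else ElasticParams()
            key = ("twed", prm.lam, prm.nu, prm.p)
        elif metric == "erp":
            key = ("erp", gap, p)
        elif metric == "ed":
            key = ("ed",)
        else:
            raise ValidationError(f"unknown metric {metric!r}")
        if key not in self._store:
            self._store[key] = pairwise_distance_matrix(
                self.xs, metric, params=params, gap=gap, p=p
            )
            self.n_computed += 1
        return self._store[key]


@dataclass
class GridResult:
    params: dict[str, float]
    t2_accuracy: float
    n_evaluations: int
    n_distance_matrices: int


def _method_distance(cache: DistanceCache, method: str, lam: float, nu: float) -> np.ndarray:
    if method in ("gtwed-svm", "1nn-twed"):
        return cache.get("twed", ElasticParams(lam=lam, nu=nu))
    if method in ("gerp-svm", "1nn-erp"):
        return cache.get("erp")
    return cache.get("ed")


def _split_t1_t2(
    labels: np.ndarray, train_idx: np.ndarray, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified single split of T into T1 (8/9) and T2 (1/9)."""
    y = labels[train_idx]
    n_classes = len(set(y))
    t2_size = max(int(np.ceil(len(train_idx) / 9)), n_classes)
    for attempt_seed in (seed, seed + 1):
        splitter = StratifiedShuffleSplit(
            n_splits=1, test_size=t2_size, random_state=attempt_seed
        )
        t1_rel, t2_rel = next(splitter.split(np.zeros(len(train_idx)), y))
        if set(y[t2_rel]) == set(y):
            return train_idx[t1_rel], train_idx[t2_rel]
    raise ValidationError("tuning split T2 is missing classes even after re-draw")


def grid_search(
    dataset: LabeledDataset,
    train_idx: np.ndarray,
    method: str,
    grid: ParamGrid | None = None,
    seed: int = 0,
    cache: DistanceCache | None = None,
) -> GridResult:
    """Tune hyperparameters on a stratified T1/T2 split of the training indices.

    Grid iteration order is lam (outer) -> nu -> sigma -> C, and ties in
    T2 accuracy keep the earlier grid point, making selection
    deterministic.
    """
    if method not in METHODS:
        raise ValidationError(f"unknown method {method!r}; choose from {METHODS}")
    if grid is None:
        grid = ParamGrid()
    if cache is None:
        cache = DistanceCache(dataset)
    labels = np.array(dataset.label_strings)
    train_idx = np.asarray(train_idx, dtype=int)
    if len(set(labels[train_idx])) < 2:
        raise ValidationError("training set must contain at least 2 classes")
    t1, t2 = _split_t1_t2(labels, train_idx, seed)
    y1, y2 = labels[t1], labels[t2]

    computed_before = cache.n_computed
    best: tuple[float, dict[str, float]] | None = None
    n_eval = 0

    if method == "1nn-ed":
        D = cache.get("ed")
        acc = float(
            np.mean(np.array(nn_predict_from_matrix(D[np.ix_(t2, t1)], y1)) == y2)
        )
        return GridResult({}, acc, 1, cache.n_computed - computed_before)
    if method == "1nn-erp":
        D = cache.get("erp")
        acc = float(
            np.mean(np.array(nn_predict_from_matrix(D[np.ix_(t2, t1)], y1)) == y2)
        )
        return GridResult({"gap": 0.0}, acc, 1, cache.n_computed - computed_before)
    if method == "1nn-twed":
        for lam, nu in product(grid.lam, grid.nu):
            D = cache.get("twed", ElasticParams(lam=lam, nu=nu))
            pred = nn_predict_from_matrix(D[np.ix_(t2, t1)], y1)
            acc = float(np.mean(np.array(pred) == y2))
            n_eval += 1
            if best is None or acc > best[0]:
                best = (acc, {"lam": lam, "nu": nu})
        assert best is not None
        return GridResult(best[1], best[0], n_eval, cache.n_computed - computed_before)

    # kernel SVMs
    lam_nu_pairs = (
        list(product(grid.lam, grid.nu)) if method == "gtwed-svm" else [(0.0, 0.0)]
    )
    for lam, nu in lam_nu_pairs:
        D = _method_distance(cache, method, lam, nu)
        D11 = D[np.ix_(t1, t1)]
        D21 = D[np.ix_(t2, t1)]
        for sigma in grid.sigma:
            K11 = kernel_from_distance(D11, sigma)
            K21 = kernel_from_distance(D21, sigma)
            for C in grid.C:
                model = train_multiclass_from_gram(K11, y1, C)
                pred = predict_from_rows(model, K21)
                acc = float(np.mean(np.array(pred) == y2))
                n_eval += 1
                point = {"sigma": sigma, "C": C}
                if method == "gtwed-svm":
                    point = {"lam": lam, "nu": nu, **point}
                if best is None or acc > best[0]:
                    best = (acc, point)
    assert best is not None
    return GridResult(best[1], best[0], n_eval, cache.n_computed - computed_before)


@dataclass
class CVReport:
    """Everything a nested cross-validation run produced."""

    method: str
    k: int
    seed: int
    fold_errors: list[float]
    fold_params: list[dict[str, float]]
    confusion: ConfusionMatrix
    per_class_aer: dict[str, float]
    total_aer: float
    protocol: str = (
        "nested stratified k-fold CV; inner stratified 8/9-1/9 T1/T2 tuning split; "
        "grid search maximizing T2 accuracy; winner refit on all of T"
    )

    def to_json(self) -> str:
        payload = {
            "method": self.method,
            "k": self.k,
            "seed": self.seed,
            "fold_errors": self.fold_errors,
            "fold_params": self.fold_params,
            "confusion": self.confusion.counts.tolist(),
            "classes": list(self.confusion.classes),
            "per_class_aer": self.per_class_aer,
            "total_aer": self.total_aer,
            "protocol": self.protocol,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n", encoding="utf-8")


def _refit_and_predict(
    dataset: LabeledDataset,
    cache: DistanceCache,
    method: str,
    params: dict[str, float],
    train_idx: np.ndarray,
    test_idx: np.ndarray,
) -> list[str]:
    labels = np.array(dataset.label_strings)
    y_train = labels[train_idx]
    lam = params.get("lam", 0.0)
    nu = params.get("nu", 0.0)
    D = _method_distance(cache, method, lam, nu)
    D_tt = D[np.ix_(test_idx, train_idx)]
    if method.startswith("1nn"):
        return nn_predict_from_matrix(D_tt, y_train)
    sigma = params["sigma"]
    K_train = kernel_from_distance(D[np.ix_(train_idx, train_idx)], sigma)
    K_test = kernel_from_distance(D_tt, sigma)
    model = train_multiclass_from_gram(K_train, y_train, params["C"])
    return predict_from_rows(model, K_test)


def nested_cv(
    dataset: LabeledDataset,
    method: str,
    grid: ParamGrid | None = None,
    k: int = 10,
    seed: int = 0,
    stratify: bool = True,
    cache: DistanceCache | None = None,
) -> CVReport:
    """Nested k-fold cross-validation of one method; fully seeded."""
    if method not in METHODS:
        raise ValidationError(f"unknown method {method!r}; choose from {METHODS}")
    if grid is None:
        grid = ParamGrid()
    if cache is None:
        cache = DistanceCache(dataset)
    labels = np.array(dataset.label_strings)
    folds = stratified_kfold(dataset, k=k, seed=seed, stratify=stratify)
    all_idx = np.arange(len(dataset))
    fold_errors: list[float] = []
    fold_params: list[dict[str, float]] = []
    actual_all: list[str] = []
    pred_all: list[str] = []
    for f, test_idx in enumerate(folds):
        try:
            train_idx = np.setdiff1d(all_idx, test_idx)
            result = grid_search(dataset, train_idx, method, grid, seed=seed, cache=cache)
            pred = _refit_and_predict(
                dataset, cache, method, result.params, train_idx, test_idx
            )
        except Exception as exc:
            raise ValidationError(f"fold {f}: {exc}") from exc
        y_test = labels[test_idx]
        fold_errors.append(float(np.mean(np.array(pred) != y_test)))
        fold_params.append(result.params)
        actual_all.extend(y_test)
        pred_all.extend(pred)
    confusion = ConfusionMatrix.from_predictions(actual_all, pred_all)
    aer = aer_from_confusion(confusion)
    return CVReport(
        method=method,
        k=k,
        seed=seed,
        fold_errors=fold_errors,
        fold_params=fold_params,
        confusion=confusion,
        per_class_aer=aer.per_class,
        total_aer=aer.total,
    )


def render_report(report: CVReport) -> str:
    """Plain-text rendering: confusion matrix plus per-class/total AER tables.

    Percentages are shown to 2 decimals with round-half-even.  When
    rendering published tables with inconsistent rows, pass explicit
    class totals to :func:`aer_from_confusion` instead of trusting the
    row sums.
    """
    cm = report.confusion
    width = max(9, *(len(c) for c in cm.classes))
    lines = [f"Method: {report.method}   (k={report.k}, seed={report.seed})", ""]
    header = " " * width + "".join(f"{c:>{width + 2}}" for c in cm.classes)
    lines.append("Confusion matrix (rows = actual, columns = predicted)")
    lines.append(header)
    for i, c in enumerate(cm.classes):
        row = "".join(f"{int(v):>{width + 2}}" for v in cm.counts[i])
        lines.append(f"{c:<{width}}{row}")
    lines.append("")
    lines.append("Per-class AER (%)")
    for c in cm.classes:
        lines.append(f"  {c:<{width}} {report.per_class_aer[c]:.2f}")
    lines.append(f"Total AER (%)   {report.total_aer:.2f}")
    lines.append("")
    lines.append("Per-fold error rates: " + ", ".join(f"{e:.4f}" for e in report.fold_errors))
    return "\n".join(lines)
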