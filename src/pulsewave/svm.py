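"""Kernel SVM on precomputed elastic Grams, and 1-NN baselines.

The binary machine solves the standard soft-margin dual

    max_a  sum_i a_i - 1/2 sum_ij a_i a_j y_i y_j k(x_i, x_j)
    s.t.   0 <= a_i <= C,   sum_i a_i y_i = 0,

and the decision function is f(z) = sum_i a_i y_i k(x_i, z) + b, with
the predicted binary label sign(f(z)).  The dual is solved by libsvm's
SMO (scikit-learn ``SVC`` with a precomputed kernel); the contract here
is the KKT tolerance, not the algorithm, and the test suite checks the
extracted multipliers against an independent QP oracle.  With an
indefinite Gram (elastic kernels are not guaranteed Mercer) SMO still
terminates, but only the metric-kernel construction — not convexity —
justifies the solution; see ``kernels.psd_diagnostics``.

Multiclass classification uses one-vs-one voting over all class pairs,
with ties broken first by the larger summed |decision value| and then
by the fixed class order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .core import (
    CLASS_ORDER,
    LabeledDataset,
    PulseLabel,
    PulsePeriod,
    TimeSeries,
    ValidationError,
)
from .kernels import GramMatrix, KernelParams, kernel_from_distance
from .metrics import ElasticParams, cross_distance_matrix, pairwise_distance_matrix

#: Multipliers smaller than this are dropped from the stored model.
ALPHA_PRUNE = 1e-8


@dataclass
class SVMModel:
    """A trained binary machine: support expansion coefficients and bias."""

    coef: np.ndarray  # alpha_i * y_i per support sample
    bias: float
    support: np.ndarray  # indices into the training set
    C: float
    kernel_params: KernelParams | None = None

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        self.support = np.asarray(self.support, dtype=int)
        if len(self.coef) != len(self.support):
            raise ValidationError("one coefficient per support sample required")


def _gram_entries(gram: GramMatrix | np.ndarray) -> np.ndarray:
    K = gram.entries if isinstance(gram, GramMatrix) else np.asarray(gram, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValidationError(f"Gram matrix must be square, got shape {K.shape}")
    return K


def train_binary_svm(
    gram: GramMatrix | np.ndarray,
    labels: Sequence[int] | np.ndarray,
    C: float,
    tol: float = 1e-3,
    kernel_params: KernelParams | None = None,
) -> SVMModel:
    """Solve the box-constrained dual on a precomputed Gram.

    ``labels`` must be +/-1 with both classes present.  The returned
    model stores only samples with non-negligible multipliers; the bias
    follows the free-support-vector rule.
    """
    K = _gram_entries(gram)
    y = np.asarray(labels, dtype=int)
    if len(y) != K.shape[0]:
        raise ValidationError("labels length does not match Gram size")
    if not set(np.unique(y)) == {-1, 1}:
        if set(np.unique(y)) <= {-1, 1}:
            raise ValidationError("both classes (+1 and -1) must be present")
        raise ValidationError("labels must be +/-1")
    if not (C > 0):
        raise ValidationError(f"C must be > 0, got {C}")
    svc = SVC(C=C, kernel="precomputed", tol=tol)
    svc.fit(K, y)
    coef = svc.dual_coef_[0].copy()
    support = svc.support_.copy()
    keep = np.abs(coef) > ALPHA_PRUNE
    coef, support = coef[keep], support[keep]
    if len(coef) == 0:
        raise ValidationError("solver returned no support vectors")
    if np.any(np.abs(coef) > C + 1e-6) or abs(coef.sum()) > 1e-6 * max(1.0, C):
        raise ValidationError(
            "solver output violates dual feasibility; the Gram may be badly "
            "indefinite — run kernels.psd_diagnostics and consider repair()"
        )
    # libsvm's decision orients positive scores toward classes_[1] == +1
    return SVMModel(
        coef=coef,
        bias=float(svc.intercept_[0]),
        support=support,
        C=float(C),
        kernel_params=kernel_params,
    )


def decision_value(model: SVMModel, kernel_row: Sequence[float] | np.ndarray) -> float:
    """Decision function sum_i (a_i y_i) k(x_i, z) + b for one query z.

    ``kernel_row`` must give k(x_i, z) for every *support* sample, in
    the model's support order.
    """
    row = np.asarray(kernel_row, dtype=float)
    if row.shape != model.coef.shape:
        raise ValidationError(
            f"kernel_row length {row.shape} does not match support count {model.coef.shape}"
        )
    return float(model.coef @ row + model.bias)


def dual_objective(
    alpha: np.ndarray, y: np.ndarray, K: np.ndarray
) -> float:
    """Dual objective W(a) = sum a - 1/2 a^T (yy^T o K) a (for tests/diagnostics)."""
    alpha = np.asarray(alpha, dtype=float)
    y = np.asarray(y, dtype=float)
    Q = (y[:, None] * y[None, :]) * np.asarray(K, dtype=float)
    return float(alpha.sum() - 0.5 * alpha @ Q @ alpha)


def model_alphas(model: SVMModel, n_train: int) -> np.ndarray:
    """Expand a model's pruned coefficients back to a full alpha vector (alpha >= 0)."""
    alpha = np.zeros(n_train)
    alpha[model.support] = np.abs(model.coef)
    return alpha


@dataclass
class MulticlassModel:
    """One-vs-one ensemble of binary machines over the present classes."""

    classes: tuple[str, ...]
    machines: dict[tuple[str, str], SVMModel]
    pair_indices: dict[tuple[str, str], np.ndarray]  # training indices per machine
    kernel_params: KernelParams | None = None
    C: float = 1.0
    training: LabeledDataset | None = None

    def __post_init__(self) -> None:
        k = len(self.classes)
        if len(self.machines) != k * (k - 1) // 2:
            raise ValidationError(
                f"expected {k * (k - 1) // 2} binary machines for {k} classes, "
                f"got {len(self.machines)}"
            )


def train_multiclass_from_gram(
    K: np.ndarray,
    labels: Sequence[str],
    C: float,
    kernel_params: KernelParams | None = None,
    tol: float = 1e-3,
) -> MulticlassModel:
    """Train one binary machine per unordered class pair on the pair's sub-Gram."""
    K = _gram_entries(K)
    labels = list(labels)
    present = tuple(c for c in CLASS_ORDER if c in set(labels))
    if len(present) < 2:
        raise ValidationError("at least 2 classes required")
    y_arr = np.array(labels)
    machines: dict[tuple[str, str], SVMModel] = {}
    pair_indices: dict[tuple[str, str], np.ndarray] = {}
    for ci, cj in combinations(present, 2):
        idx = np.flatnonzero((y_arr == ci) | (y_arr == cj))
        y_bin = np.where(y_arr[idx] == ci, 1, -1)
        sub = K[np.ix_(idx, idx)]
        machines[(ci, cj)] = train_binary_svm(
            sub, y_bin, C, tol=tol, kernel_params=kernel_params
        )
        pair_indices[(ci, cj)] = idx
    return MulticlassModel(
        classes=present,
        machines=machines,
        pair_indices=pair_indices,
        kernel_params=kernel_params,
        C=float(C),
    )


def train_multiclass(
    dataset: LabeledDataset,
    kp: KernelParams,
    C: float,
    distance_matrix: np.ndarray | None = None,
) -> MulticlassModel:
    """Compute the elastic Gram over a dataset and train the one-vs-one ensemble."""
    xs = [p.to_timeseries() for p in dataset.periods]
    if distance_matrix is None:
        if kp.metric == "twed":
            distance_matrix = pairwise_distance_matrix(xs, "twed", params=kp.elastic)
        else:
            distance_matrix = pairwise_distance_matrix(xs, kp.metric, gap=kp.gap, p=kp.p)
    K = kernel_from_distance(distance_matrix, kp.sigma)
    model = train_multiclass_from_gram(K, dataset.label_strings, C, kernel_params=kp)
    model.training = dataset
    return model


def predict_from_rows(model: MulticlassModel, kernel_rows: np.ndarray) -> list[str]:
    """Predict class labels from kernel rows k(x_train, z) for each query.

    ``kernel_rows`` has shape (n_queries, n_train) in training order.
    """
    rows = np.atleast_2d(np.asarray(kernel_rows, dtype=float))
    n_q = rows.shape[0]
    votes = {c: np.zeros(n_q, dtype=int) for c in model.classes}
    strength = {c: np.zeros(n_q) for c in model.classes}
    for (ci, cj), machine in model.machines.items():
        idx = model.pair_indices[(ci, cj)]
        sub_rows = rows[:, idx[machine.support]]
        dec = sub_rows @ machine.coef + machine.bias
        pos = dec >= 0
        votes[ci] += pos
        votes[cj] += ~pos
        strength[ci] += np.abs(dec) * pos
        strength[cj] += np.abs(dec) * ~pos
    out: list[str] = []
    for q in range(n_q):
        best = max(votes[c][q] for c in model.classes)
        tied = [c for c in model.classes if votes[c][q] == best]
        if len(tied) > 1:
            top = max(strength[c][q] for c in tied)
            tied = [c for c in tied if strength[c][q] == top]
        # model.classes follows CLASS_ORDER, so tied[0] is the fixed-order winner
        out.append(tied[0])
    return out


def predict(model: MulticlassModel, z: PulsePeriod) -> PulseLabel:
    """Predict the class of one normalized period (requires stored training data)."""
    if model.training is None or model.kernel_params is None:
        raise ValidationError("model lacks stored training periods; use predict_from_rows")
    kp = model.kernel_params
    xs = [p.to_timeseries() for p in model.training.periods]
    if kp.metric == "twed":
        d = cross_distance_matrix([z.to_timeseries()], xs, "twed", params=kp.elastic)
    else:
        d = cross_distance_matrix([z.to_timeseries()], xs, kp.metric, gap=kp.gap, p=kp.p)
    rows = kernel_from_distance(d, kp.sigma)
    return PulseLabel(predict_from_rows(model, rows)[0])


# ---------------------------------------------------------------------------
# 1-nearest-neighbor baselines
# ---------------------------------------------------------------------------


def nn_predict_from_matrix(
    dist_rows: np.ndarray, train_labels: Sequence[str]
) -> list[str]:
    """1-NN labels from a (n_queries, n_train) distance matrix; ties -> lowest index."""
    rows = np.atleast_2d(np.asarray(dist_rows, dtype=float))
    idx = np.argmin(rows, axis=1)  # first minimum wins
    labels = list(train_labels)
    return [labels[i] for i in idx]


def nn_classify(
    train: LabeledDataset,
    z: PulsePeriod | TimeSeries,
    metric: str = "twed",
    params: ElasticParams | None = None,
    gap: float = 0.0,
    p: int = 1,
) -> PulseLabel:
    """Label of the training sample nearest to ``z`` under the chosen metric."""
    if len(train) == 0:
        raise ValidationError("empty training set")
    zs = z.to_timeseries() if isinstance(z, PulsePeriod) else z
    xs = [per.to_timeseries() for per in train.periods]
    d = cross_distance_matrix([zs], xs, metric, params=params, gap=gap, p=p)
    return train.labels[int(np.argmin(d[0]))]


# ---------------------------------------------------------------------------
# Serialization (structured text, JSON)
# ---------------------------------------------------------------------------


def _kp_to_dict(kp: KernelParams | None) -> dict | None:
    if kp is None:
        return None
    return {
        "sigma": kp.sigma,
        "metric": kp.metric,
        "lam": kp.elastic.lam,
        "nu": kp.elastic.nu,
        "p": kp.elastic.p,
        "gap": kp.gap,
    }


def _kp_from_dict(d: dict | None) -> KernelParams | None:
    if d is None:
        return None
    return KernelParams(
        sigma=d["sigma"],
        metric=d["metric"],
        elastic=ElasticParams(lam=d["lam"], nu=d["nu"], p=d["p"]),
        gap=d["gap"],
        p=d["p"],
    )


def save_model(model: MulticlassModel, path: str | Path) -> None:
    payload = {
        "classes": list(model.classes),
        "C": model.C,
        "kernel_params": _kp_to_dict(model.kernel_params),
        "machines": {
            f"{ci}|{cj}": {
                "coef": [repr(float(v)) for v in m.coef],
                "bias": repr(float(m.bias)),
                "support": m.support.tolist(),
                "C": m.C,
            }
            for (ci, cj), m in model.machines.items()
        },
        "pair_indices": {
            f"{ci}|{cj}": idx.tolist() for (ci, cj), idx in model.pair_indices.items()
        },
    }
    Path(path).write_text(
        json.dumps(payload, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )


def load_model(path: str | Path) -> MulticlassModel:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    kp = _kp_from_dict(payload["kernel_params"])
    machines = {}
    pair_indices = {}
    for key, m in payload["machines"].items():
        ci, cj = key.split("|")
        machines[(ci, cj)] = SVMModel(
            coef=np.array([float(v) for v in m["coef"]]),
            bias=float(m["bias"]),
            support=np.array(m["support"], dtype=int),
            C=m["C"],
            kernel_params=kp,
        )
        pair_indices[(ci, cj)] = np.array(payload["pair_indices"][key], dtype=int)
    return MulticlassModel(
        classes=tuple(payload["classes"]),
        machines=machines,
        pair_indices=pair_indices,
        kernel_params=kp,
        C=payload["C"],
    )
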