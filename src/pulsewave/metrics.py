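"""Elastic distances between time series.

Implements the Time Warp Edit Distance (TWED), the Edit distance with
Real Penalty (ERP), and the plain Euclidean baseline, together with
independent memoized-recursion oracles used by the test suite.

TWED is an edit-style distance whose three operations (delete in A,
match, delete in B) carry costs that mix amplitude differences with
time-stamp differences:

* delete a_i:  |a_i - a_{i-1}| + nu * (t_{a_i} - t_{a_{i-1}}) + lam
* match:       |a_i - b_j| + |a_{i-1} - b_{j-1}|
               + nu * (|t_{a_i} - t_{b_j}| + |t_{a_{i-1}} - t_{b_{j-1}}|)
* delete b_j:  symmetric to delete a_i

``lam`` (edit penalty) and ``nu`` (time-stamp weight, "stiffness")
are non-negative; with both positive TWED satisfies the metric axioms,
including the triangle inequality — unlike DTW.  Both series are padded
with a virtual sample of value 0 at time 0, the standard boundary
convention of the reference formulation.

The dynamic programs are compiled with numba: a 150 x 150 table costs a
few tens of microseconds, which is what makes 247 x 247 Gram matrices
over a hyperparameter grid tractable.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from numba import njit

from .core import TimeSeries, ValidationError, make_timeseries

#: Length guard for the exponential-style oracle implementations.
BRUTEFORCE_MAX_LENGTH = 8


@dataclass(frozen=True)
class ElasticParams:
    """Stiffness parameters of TWED.

    Parameters
    ----------
    lam : float
        Edit (deletion) penalty, in signal units.  Must be >= 0.
    nu : float
        Time-stamp weight, in signal units per time unit.  Must be >= 0.
        ``nu = 0`` gives maximal elasticity, large ``nu`` approaches a
        rigid, Euclidean-like comparison.
    p : int
        Order of the L_p norm used for element costs.  For scalar-valued
        series every L_p reduces to the absolute difference; the
        parameter is exposed for multivariate extension.
    """

    lam: float = 1e-2
    nu: float = 0.25
    p: int = 1

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValidationError(f"lam must be >= 0, got {self.lam}")
        if self.nu < 0:
            raise ValidationError(f"nu must be >= 0, got {self.nu}")
        if self.p < 1:
            raise ValidationError(f"p must be >= 1, got {self.p}")


@njit(cache=True)
def _twed_dp(av, at, bv, bt, lam, nu):  # pragma: no cover - compiled
    m = av.shape[0]
    n = bv.shape[0]
    # padded element: value 0 at time 0 (index 0 of the padded arrays)
    pa = np.empty(m + 1)
    pta = np.empty(m + 1)
    pb = np.empty(n + 1)
    ptb = np.empty(n + 1)
    pa[0] = 0.0
    pta[0] = 0.0
    pb[0] = 0.0
    ptb[0] = 0.0
    pa[1:] = av
    pta[1:] = at
    pb[1:] = bv
    ptb[1:] = bt

    D = np.empty((m + 1, n + 1))
    D[0, 0] = 0.0
    for i in range(1, m + 1):
        D[i, 0] = D[i - 1, 0] + abs(pa[i] - pa[i - 1]) + nu * (pta[i] - pta[i - 1]) + lam
    for j in range(1, n + 1):
        D[0, j] = D[0, j - 1] + abs(pb[j] - pb[j - 1]) + nu * (ptb[j] - ptb[j - 1]) + lam

    for i in range(1, m + 1):
        for j in range(1, n + 1):
            del_a = D[i - 1, j] + abs(pa[i] - pa[i - 1]) + nu * (pta[i] - pta[i - 1]) + lam
            match = (
                D[i - 1, j - 1]
                + abs(pa[i] - pb[j])
                + abs(pa[i - 1] - pb[j - 1])
                + nu * (abs(pta[i] - ptb[j]) + abs(pta[i - 1] - ptb[j - 1]))
            )
            del_b = D[i, j - 1] + abs(pb[j] - pb[j - 1]) + nu * (ptb[j] - ptb[j - 1]) + lam
            best = del_a
            if match < best:
                best = match
            if del_b < best:
                best = del_b
            D[i, j] = best
    return D[m, n]


@njit(cache=True)
def _erp_dp(av, bv, gap):  # pragma: no cover - compiled
    m = av.shape[0]
    n = bv.shape[0]
    D = np.empty((m + 1, n + 1))
    D[0, 0] = 0.0
    for i in range(1, m + 1):
        D[i, 0] = D[i - 1, 0] + abs(av[i - 1] - gap)
    for j in range(1, n + 1):
        D[0, j] = D[0, j - 1] + abs(bv[j - 1] - gap)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            del_a = D[i - 1, j] + abs(av[i - 1] - gap)
            del_b = D[i, j - 1] + abs(bv[j - 1] - gap)
            match = D[i - 1, j - 1] + abs(av[i - 1] - bv[j - 1])
            best = del_a
            if match < best:
                best = match
            if del_b < best:
                best = del_b
            D[i, j] = best
    return D[m, n]


def _check_series(x: TimeSeries, name: str) -> None:
    if not isinstance(x, TimeSeries):
        raise ValidationError(f"{name} must be a TimeSeries, got {type(x).__name__}")


def twed_distance(a: TimeSeries, b: TimeSeries, params: ElasticParams) -> float:
    """Time Warp Edit Distance between two series (iterative DP)."""
    _check_series(a, "a")
    _check_series(b, "b")
    if not isinstance(params, ElasticParams):
        raise ValidationError("params must be ElasticParams")
    return float(
        _twed_dp(a.values, a.timestamps, b.values, b.timestamps, params.lam, params.nu)
    )


def twed_bruteforce(a: TimeSeries, b: TimeSeries, params: ElasticParams) -> float:
    """Direct memoized transcription of the TWED recursion.

    Exists solely as an independent oracle for equivalence testing;
    guarded to short series.
    """
    _check_series(a, "a")
    _check_series(b, "b")
    if len(a) > BRUTEFORCE_MAX_LENGTH or len(b) > BRUTEFORCE_MAX_LENGTH:
        raise ValidationError(
            f"bruteforce oracle limited to series of length <= {BRUTEFORCE_MAX_LENGTH}"
        )
    pa = np.concatenate(([0.0], a.values))
    pta = np.concatenate(([0.0], a.timestamps))
    pb = np.concatenate(([0.0], b.values))
    ptb = np.concatenate(([0.0], b.timestamps))
    lam, nu = params.lam, params.nu

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> float:
        if i == 0 and j == 0:
            return 0.0
        candidates = []
        if i >= 1:
            candidates.append(
                rec(i - 1, j) + abs(pa[i] - pa[i - 1]) + nu * (pta[i] - pta[i - 1]) + lam
            )
        if i >= 1 and j >= 1:
            candidates.append(
                rec(i - 1, j - 1)
                + abs(pa[i] - pb[j])
                + abs(pa[i - 1] - pb[j - 1])
                + nu * (abs(pta[i] - ptb[j]) + abs(pta[i - 1] - ptb[j - 1]))
            )
        if j >= 1:
            candidates.append(
                rec(i, j - 1) + abs(pb[j] - pb[j - 1]) + nu * (ptb[j] - ptb[j - 1]) + lam
            )
        return min(candidates)

    return float(rec(len(a), len(b)))


def erp_distance(a: TimeSeries, b: TimeSeries, gap: float = 0.0, p: int = 1) -> float:
    """Edit distance with Real Penalty, constant gap element (default 0)."""
    _check_series(a, "a")
    _check_series(b, "b")
    if p < 1:
        raise ValidationError(f"p must be >= 1, got {p}")
    return float(_erp_dp(a.values, b.values, float(gap)))


def erp_bruteforce(a: TimeSeries, b: TimeSeries, gap: float = 0.0, p: int = 1) -> float:
    """Memoized naive ERP recursion — the test oracle for :func:`erp_distance`."""
    _check_series(a, "a")
    _check_series(b, "b")
    if len(a) > BRUTEFORCE_MAX_LENGTH or len(b) > BRUTEFORCE_MAX_LENGTH:
        raise ValidationError(
            f"bruteforce oracle limited to series of length <= {BRUTEFORCE_MAX_LENGTH}"
        )
    av, bv = a.values, b.values
    g = float(gap)

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> float:
        if i == 0 and j == 0:
            return 0.0
        candidates = []
        if i >= 1:
            candidates.append(rec(i - 1, j) + abs(av[i - 1] - g))
        if j >= 1:
            candidates.append(rec(i, j - 1) + abs(bv[j - 1] - g))
        if i >= 1 and j >= 1:
            candidates.append(rec(i - 1, j - 1) + abs(av[i - 1] - bv[j - 1]))
        return min(candidates)

    return float(rec(len(a), len(b)))


def euclidean_distance(a: TimeSeries, b: TimeSeries) -> float:
    """Euclidean distance of two equal-length series (the non-elastic baseline)."""
    _check_series(a, "a")
    _check_series(b, "b")
    if len(a) != len(b):
        raise ValidationError(
            f"Euclidean distance requires equal lengths, got {len(a)} and {len(b)}"
        )
    return float(np.linalg.norm(a.values - b.values))


METRICS = ("twed", "erp", "ed")


def _metric_fn(metric: str, params: ElasticParams | None, gap: float, p: int):
    if metric == "twed":
        prm = params if params is not None else ElasticParams()
        return lambda x, y: twed_distance(x, y, prm)
    if metric == "erp":
        return lambda x, y: erp_distance(x, y, gap=gap, p=p)
    if metric == "ed":
        return euclidean_distance
    raise ValidationError(f"unknown metric {metric!r}; choose from {METRICS}")


def pairwise_distance_matrix(
    xs: Sequence[TimeSeries],
    metric: str = "twed",
    params: ElasticParams | None = None,
    gap: float = 0.0,
    p: int = 1,
) -> np.ndarray:
    """Symmetric matrix of pairwise distances, each unordered pair computed once."""
    if len(xs) == 0:
        raise ValidationError("empty collection")
    fn = _metric_fn(metric, params, gap, p)
    n = len(xs)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = fn(xs[i], xs[j])
            except Exception as exc:
                raise ValidationError(f"metric failed for pair ({i}, {j}): {exc}") from exc
            M[i, j] = d
            M[j, i] = d
    return M


def cross_distance_matrix(
    xs: Sequence[TimeSeries],
    ys: Sequence[TimeSeries],
    metric: str = "twed",
    params: ElasticParams | None = None,
    gap: float = 0.0,
    p: int = 1,
) -> np.ndarray:
    """Rectangular matrix ``M[i, j] = d(xs[i], ys[j])``."""
    fn = _metric_fn(metric, params, gap, p)
    M = np.empty((len(xs), len(ys)))
    for i, x in enumerate(xs):
        for j, y in enumerate(ys):
            M[i, j] = fn(x, y)
    return M


def periods_to_timeseries(values_matrix: np.ndarray) -> list[TimeSeries]:
    """Wrap the rows of an ``(n, L)`` sample matrix as TimeSeries with index stamps."""
    return [make_timeseries(row) for row in np.asarray(values_matrix, dtype=float)]


def write_matrix_tsv(
    matrix: np.ndarray, ids: Sequence[str], path, comment: str | None = None
) -> None:
    """Serialize a full square matrix as TSV with a header row of identifiers."""
    lines = []
    if comment:
        lines.append(f"# {comment}")
    lines.append("\t".join(["id", *ids]))
    for name, row in zip(ids, np.asarray(matrix)):
        lines.append("\t".join([name, *[repr(float(v)) for v in row]]))
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_matrix_tsv(path) -> tuple[np.ndarray, list[str]]:
    rows = []
    ids: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        header: list[str] | None = None
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = parts[1:]
                continue
            ids.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    return np.array(rows), ids
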