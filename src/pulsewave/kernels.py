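"""Gaussian elastic kernels and Gram-matrix machinery.

The Gaussian-TWED kernel embeds the TWED metric in a Gaussian:

    k(A, B) = exp(-d_twed(A, B)^2 / (2 sigma^2))

and the Gaussian-ERP kernel does the same with the ERP metric.  Because
both underlying distances are true metrics, these kernels avoid the
known failure mode of the Gaussian-DTW kernel (DTW violates the
triangle inequality, and a Gaussian of a non-metric is provably not
positive definite).  Metricity is only a *necessary* condition for
positive definiteness, so this module reports — and never assumes —
definiteness; :func:`psd_diagnostics` measures the smallest eigenvalue
and :func:`repair` offers spectrum clipping and diagonal jitter for
callers that require a Mercer kernel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import TimeSeries, ValidationError
from .metrics import (
    ElasticParams,
    erp_distance,
    pairwise_distance_matrix,
    twed_distance,
)

logger = logging.getLogger(__name__)

#: Eigenvalues above this (negative) tolerance are treated as numerical noise.
PSD_TOL = 1e-8


@dataclass(frozen=True)
class KernelParams:
    """Bandwidth and underlying-metric parameters of an elastic kernel."""

    sigma: float = 1.0
    metric: str = "twed"
    elastic: ElasticParams = field(default_factory=ElasticParams)
    gap: float = 0.0
    p: int = 1

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValidationError(f"sigma must be > 0, got {self.sigma}")
        if self.metric not in ("twed", "erp", "ed"):
            raise ValidationError(f"unknown kernel metric {self.metric!r}")


def kernel_from_distance(d: float | np.ndarray, sigma: float) -> float | np.ndarray:
    """Gaussian transform ``exp(-d^2 / (2 sigma^2))`` of a distance."""
    if not (sigma > 0):
        raise ValidationError(f"sigma must be > 0, got {sigma}")
    d = np.asarray(d, dtype=float)
    out = np.exp(-(d**2) / (2.0 * sigma**2))
    return float(out) if out.ndim == 0 else out


def gtwed_kernel(a: TimeSeries, b: TimeSeries, kp: KernelParams) -> float:
    """Gaussian-TWED kernel value in (0, 1]."""
    return float(kernel_from_distance(twed_distance(a, b, kp.elastic), kp.sigma))


def gerp_kernel(a: TimeSeries, b: TimeSeries, kp: KernelParams) -> float:
    """Gaussian-ERP kernel value in (0, 1]."""
    return float(kernel_from_distance(erp_distance(a, b, gap=kp.gap, p=kp.p), kp.sigma))


@dataclass(frozen=True)
class GramMatrix:
    """Symmetric matrix of pairwise kernel values with its generating params."""

    entries: np.ndarray
    ids: tuple[str, ...]
    params: KernelParams

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=float)
        if entries.ndim != 2 or entries.shape[0] != entries.shape[1]:
            raise ValidationError(f"Gram matrix must be square, got shape {entries.shape}")
        if len(self.ids) != entries.shape[0]:
            raise ValidationError("ids length does not match matrix size")
        if not np.allclose(entries, entries.T, atol=1e-12, rtol=0.0):
            raise ValidationError("Gram matrix is not symmetric within 1e-12")
        if not np.allclose(np.diag(entries), 1.0, atol=1e-6):
            raise ValidationError("Gram diagonal must equal 1")
        entries.setflags(write=False)
        object.__setattr__(self, "entries", entries)
        object.__setattr__(self, "ids", tuple(self.ids))

    @property
    def n(self) -> int:
        return self.entries.shape[0]


def gram_matrix(
    xs: Sequence[TimeSeries],
    kp: KernelParams,
    cache: np.ndarray | None = None,
    ids: Sequence[str] | None = None,
) -> GramMatrix:
    """Gram matrix of an elastic kernel over a collection of series.

    ``cache`` may supply a precomputed pairwise distance matrix for the
    same metric parameters, in which case the dynamic program is not
    re-run — sweeping sigma (or the SVM's C) then costs only an
    elementwise exponential.
    """
    if len(xs) == 0:
        raise ValidationError("empty collection")
    if cache is not None:
        cache = np.asarray(cache, dtype=float)
        if cache.shape != (len(xs), len(xs)):
            raise ValidationError(
                f"cache shape {cache.shape} does not match collection size {len(xs)}"
            )
        D = cache
    else:
        if kp.metric == "twed":
            D = pairwise_distance_matrix(xs, metric="twed", params=kp.elastic)
        else:
            D = pairwise_distance_matrix(xs, metric=kp.metric, gap=kp.gap, p=kp.p)
    K = kernel_from_distance(D, kp.sigma)
    # enforce exact symmetry and unit diagonal against float round-off
    K = 0.5 * (K + K.T)
    np.fill_diagonal(K, 1.0)
    if ids is None:
        ids = [str(i) for i in range(len(xs))]
    return GramMatrix(entries=K, ids=tuple(ids), params=kp)


@dataclass(frozen=True)
class PsdReport:
    min_eigenvalue: float
    is_psd_within_tol: bool


def _entries(g: GramMatrix | np.ndarray) -> np.ndarray:
    return g.entries if isinstance(g, GramMatrix) else np.asarray(g, dtype=float)


def psd_diagnostics(g: GramMatrix | np.ndarray, tol: float = PSD_TOL) -> PsdReport:
    """Smallest eigenvalue of the symmetrized Gram and a PSD flag.

    A Mercer (positive definite symmetric) kernel is what guarantees the
    SVM dual is convex; an indefinite Gram can still train but without a
    global-optimum guarantee, so callers should log this report.
    """
    K = _entries(g)
    K = 0.5 * (K + K.T)
    w = np.linalg.eigvalsh(K)
    min_eig = float(w[0])
    return PsdReport(min_eigenvalue=min_eig, is_psd_within_tol=min_eig >= -tol)


REPAIR_MODES = ("none", "clip", "jitter")


def repair(g: GramMatrix, mode: str = "none", tol: float = PSD_TOL) -> GramMatrix:
    """Return a positive-semidefinite surrogate of an indefinite Gram.

    Modes: ``"none"`` returns the matrix unchanged (logging a warning if
    indefinite); ``"clip"`` zeroes negative eigenvalues and reconstitutes;
    ``"jitter"`` shifts the whole diagonal by ``|min_eig| + tol``.  After
    either repair the diagonal is re-normalized to 1.
    """
    if mode not in REPAIR_MODES:
        raise ValidationError(f"unknown repair mode {mode!r}; choose from {REPAIR_MODES}")
    K = np.array(_entries(g), dtype=float)
    K = 0.5 * (K + K.T)
    w, V = np.linalg.eigh(K)
    min_eig = float(w[0])
    if mode == "none":
        if min_eig < -tol:
            logger.warning(
                "Gram matrix is indefinite (min eigenvalue %.3e); training proceeds "
                "on the raw matrix — consider repair mode 'clip' or 'jitter'",
                min_eig,
            )
        return g
    if mode == "clip":
        K2 = (V * np.clip(w, 0.0, None)) @ V.T
    else:  # jitter
        shift = abs(min_eig) + tol if min_eig < 0 else tol
        K2 = K + shift * np.eye(K.shape[0])
    # re-normalize the diagonal to 1 (unit self-similarity)
    d = np.sqrt(np.clip(np.diag(K2), 1e-300, None))
    K2 = K2 / np.outer(d, d)
    K2 = 0.5 * (K2 + K2.T)
    np.fill_diagonal(K2, 1.0)
    return GramMatrix(entries=K2, ids=g.ids, params=g.params)


def write_gram_tsv(g: GramMatrix, path) -> None:
    from .metrics import write_matrix_tsv

    kp = g.params
    comment = (
        f"kernel metric={kp.metric} sigma={kp.sigma!r} lam={kp.elastic.lam!r} "
        f"nu={kp.elastic.nu!r} p={kp.elastic.p} gap={kp.gap!r}"
    )
    write_matrix_tsv(g.entries, list(g.ids), path, comment=comment)
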