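"""Pearson-correlation brain functional networks and the iterated PC^n map.

A brain functional network (BFN) is an N x N symmetric matrix whose entry
(i, j) measures the statistical dependence between the fMRI time series of
ROIs i and j.  The ordinary Pearson network (``PC^1``) is

    R_1 = X^T X

for a column-wise centered, unit-norm data matrix X (M time points x N
ROIs).  Higher-order networks are obtained by *iterating* the correlation:
each row of R_{n-1} is treated as a new "signal" attached to its ROI, and
the Pearson correlation of those rows yields R_n.  In matrix form one step
of the map is

    R_n = D^{-1/2} (R_{n-1} C R_{n-1}) D^{-1/2},
    C   = I - E/N,   D = diag(R_{n-1} C R_{n-1}),

with E the all-ones matrix and C the (symmetric, idempotent) centering
matrix.  Empirically the sequence {R_n} converges, within a few dozen
iterations, to a binary matrix with off-diagonal entries +-1; this module
instruments that convergence (per-step deltas, a "binariness" score) while
:mod:`pcn.diagnostics` tracks ranks, sign changes and fixed points.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "DegenerateSignalError",
    "ROITimeSeries",
    "AdjacencyMatrix",
    "ConvergenceReport",
    "BFNSequence",
    "standardize_signals",
    "pearson_bfn",
    "centering_matrix",
    "pcn_step",
    "pcn_sequence",
    "converged_bfn",
    "binariness_score",
    "DEFAULT_TOL",
    "DEFAULT_MAX_ITER",
]

#: Convergence tolerance on the max-abs elementwise difference between
#: consecutive matrices.
DEFAULT_TOL = 1e-6

#: Iteration cap for the empirical convergence run.
DEFAULT_MAX_ITER = 30

#: Threshold below which a diagonal entry of R C R is considered degenerate
#: (the corresponding row of R was constant, so its centered norm vanishes).
DEGENERACY_EPS = 1e-12


class ValidationError(ValueError):
    """Invalid input data or configuration."""


class DegenerateSignalError(ValidationError):
    """A signal (ROI column, or matrix row acting as a signal) is constant.

    Pearson correlation is undefined for constant signals.  The ``order``
    attribute, when set, records the iteration order at which the
    degeneracy arose.
    """

    def __init__(self, message: str, nodes: Sequence[int] = (), order: Optional[int] = None):
        super().__init__(message)
        self.nodes = tuple(int(i) for i in nodes)
        self.order = order


def _as_float_matrix(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValidationError(f"{name} must be a 2-D matrix, got ndim={arr.ndim}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite entries")
    return arr


@dataclass(frozen=True)
class ROITimeSeries:
    """One scan's ROI-level signal matrix with subject/label metadata.

    Parameters
    ----------
    values
        M x N real matrix: rows are time points, columns are ROIs
        (dimensionless BOLD units).
    scan_id, subject_id
        Identifiers; several scans may share one ``subject_id``.
    label
        Optional binary class label for the scan's subject.
    roi_names
        Optional ROI names (length N).
    """

    values: np.ndarray
    scan_id: str = "scan"
    subject_id: str = ""
    label: Optional[str] = None
    roi_names: Optional[tuple[str, ...]] = None

    def __post_init__(self):
        arr = _as_float_matrix(self.values, "time series")
        if arr.shape[0] < 3:
            raise ValidationError(f"need at least 3 time points, got {arr.shape[0]}")
        if arr.shape[1] < 2:
            raise ValidationError(f"need at least 2 ROIs, got {arr.shape[1]}")
        if self.roi_names is not None:
            names = tuple(str(n) for n in self.roi_names)
            if len(names) != arr.shape[1]:
                raise ValidationError(
                    f"{len(names)} ROI names for {arr.shape[1]} columns"
                )
            object.__setattr__(self, "roi_names", names)
        object.__setattr__(self, "values", arr)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class AdjacencyMatrix:
    """N x N correlation matrix of a BFN at a given order.

    Invariants (checked at construction): symmetric to 1e-12, diagonal
    exactly 1, all entries in [-1, 1].  ``degenerate_nodes`` lists ROI
    indices whose signal/row was constant at some order <= this one (their
    off-diagonal entries are zero-filled under the "zero" policy).
    """

    values: np.ndarray
    order: int
    degenerate_nodes: frozenset = frozenset()

    def __post_init__(self):
        arr = _as_float_matrix(self.values, "adjacency matrix")
        n = arr.shape[0]
        if arr.shape[1] != n or n < 2:
            raise ValidationError(f"adjacency matrix must be square with N >= 2, got {arr.shape}")
        if self.order < 1:
            raise ValidationError(f"order must be >= 1, got {self.order}")
        if np.abs(arr - arr.T).max() > 1e-12:
            raise ValidationError("adjacency matrix is not symmetric to 1e-12")
        if not np.all(np.diag(arr) == 1.0):
            raise ValidationError("adjacency matrix diagonal must be exactly 1")
        if arr.min() < -1.0 or arr.max() > 1.0:
            raise ValidationError("adjacency matrix entries must lie in [-1, 1]")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "degenerate_nodes", frozenset(int(i) for i in self.degenerate_nodes))

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ConvergenceReport:
    """Bookkeeping for one PC^n iteration run.

    ``step_deltas[k]`` is ``max|R_{k+2} - R_{k+1}|`` (one entry per
    iteration performed); ``binariness[k]`` scores R_{k+1}.  When
    ``converged`` is true, ``n_converged`` is the first order n with
    ``step_deltas[n-2] < tol``.
    """

    converged: bool
    n_converged: Optional[int]
    step_deltas: tuple[float, ...]
    binariness: tuple[float, ...]
    tol: float
    max_iter: int

    def __post_init__(self):
        object.__setattr__(self, "step_deltas", tuple(float(d) for d in self.step_deltas))
        object.__setattr__(self, "binariness", tuple(float(b) for b in self.binariness))
        if self.converged:
            if self.n_converged is None or self.n_converged < 2:
                raise ValidationError("converged report needs n_converged >= 2")
            if not self.step_deltas[self.n_converged - 2] < self.tol:
                raise ValidationError("n_converged inconsistent with step_deltas/tol")

    def to_dict(self) -> dict:
        return {
            "converged": self.converged,
            "n_converged": self.n_converged,
            "step_deltas": list(self.step_deltas),
            "binariness": list(self.binariness),
            "tol": self.tol,
            "max_iter": self.max_iter,
        }


@dataclass(frozen=True)
class BFNSequence:
    """Ordered BFN matrices at orders 1..n plus a convergence report."""

    matrices: tuple[AdjacencyMatrix, ...]
    report: ConvergenceReport

    def __post_init__(self):
        mats = tuple(self.matrices)
        if not mats:
            raise ValidationError("empty BFN sequence")
        for k, m in enumerate(mats):
            if m.order != k + 1:
                raise ValidationError("sequence orders must be consecutive starting at 1")
            if m.n_rois != mats[0].n_rois:
                raise ValidationError("all matrices in a sequence must share one N")
        object.__setattr__(self, "matrices", mats)

    def __len__(self) -> int:
        return len(self.matrices)

    def __getitem__(self, idx: int) -> AdjacencyMatrix:
        return self.matrices[idx]

    def __iter__(self):
        return iter(self.matrices)

    @property
    def final(self) -> AdjacencyMatrix:
        return self.matrices[-1]

    @property
    def n_rois(self) -> int:
        return self.matrices[0].n_rois

    def at_order(self, order) -> AdjacencyMatrix:
        """Matrix at an integer ``order``, or the final one for ``"conv"``.

        If the sequence stopped (converged) before ``order``, the final
        matrix is returned: beyond the stopping order consecutive matrices
        differ by less than the tolerance.
        """
        if order == "conv":
            return self.final
        order = int(order)
        if order < 1:
            raise ValidationError(f"order must be >= 1, got {order}")
        if order <= len(self.matrices):
            return self.matrices[order - 1]
        return self.final


def binariness_score(values: np.ndarray) -> float:
    """Mean off-diagonal |r|: 1 means every off-diagonal entry is +-1."""
    n = values.shape[0]
    off = values[~np.eye(n, dtype=bool)]
    return float(np.mean(np.abs(off)))


def _standardized_columns(ts: ROITimeSeries, policy: str = "error"):
    """Center and unit-norm the columns; handle constant columns per policy.

    Returns ``(X, degenerate)`` where degenerate columns are zero-filled
    under the ``"zero"`` policy.
    """
    if policy not in ("error", "zero"):
        raise ValidationError(f"unknown degenerate-node policy {policy!r}")
    X = ts.values - ts.values.mean(axis=0)
    norms = np.linalg.norm(X, axis=0)
    scale = np.maximum(np.abs(ts.values).max(axis=0), 1.0)
    degenerate = norms <= DEGENERACY_EPS * math.sqrt(ts.n_timepoints) * scale
    if degenerate.any():
        idx = np.flatnonzero(degenerate)
        if policy == "error":
            raise DegenerateSignalError(
                f"constant signal in ROI column(s) {idx.tolist()}", nodes=idx
            )
        X = X.copy()
        X[:, degenerate] = 0.0
        norms = np.where(degenerate, 1.0, norms)
    return X / norms, np.flatnonzero(degenerate)


def standardize_signals(ts: ROITimeSeries, policy: str = "error") -> ROITimeSeries:
    """Center each ROI column to mean 0 and scale it to unit Euclidean norm.

    With this standardization the Pearson matrix reduces to ``X^T X``.
    Constant columns raise :class:`DegenerateSignalError` under the default
    ``"error"`` policy, or are zero-filled under ``"zero"``.
    """
    X, _ = _standardized_columns(ts, policy)
    return dataclasses.replace(ts, values=X)


def pearson_bfn(ts: ROITimeSeries, policy: str = "error") -> AdjacencyMatrix:
    """Order-1 Pearson BFN: pairwise correlation of the ROI signals."""
    X, degenerate = _standardized_columns(ts, policy)
    R = X.T @ X
    return _finalize(R, order=1, degenerate=frozenset(degenerate.tolist()))


def centering_matrix(n: int) -> np.ndarray:
    """The centering matrix ``C = I - E/N`` (symmetric, idempotent).

    Multiplying a length-N vector by C subtracts its mean; rows sum to 0.
    """
    n = int(n)
    if n < 2:
        raise ValidationError(f"centering matrix needs N >= 2, got {n}")
    return np.eye(n) - np.full((n, n), 1.0 / n)


def _finalize(R: np.ndarray, order: int, degenerate: frozenset) -> AdjacencyMatrix:
    # Round-off repair: the exact-arithmetic properties (symmetry, unit
    # diagonal, entries in [-1, 1], exact +-1 in closed-form cases) must
    # survive floating point.  Entries within ~50 ulps of +-1 are snapped.
    R = (R + R.T) / 2.0
    R[R > 1.0 - 1e-14] = 1.0
    R[R < -1.0 + 1e-14] = -1.0
    np.clip(R, -1.0, 1.0, out=R)
    np.fill_diagonal(R, 1.0)
    return AdjacencyMatrix(values=R, order=order, degenerate_nodes=degenerate)


def pcn_step(R_prev: AdjacencyMatrix, policy: str = "error") -> AdjacencyMatrix:
    """One iteration of the PC map: correlate the rows of ``R_prev``.

    Computes ``M = R C R`` with the centering matrix C and rescales by
    ``D^{-1/2} M D^{-1/2}``, ``D = diag(M)`` — exactly the Pearson
    correlation matrix of the rows of ``R_prev`` treated as signals.

    A vanishing diagonal entry of M means the corresponding row of
    ``R_prev`` was constant; the node is reported per ``policy``.
    """
    if policy not in ("error", "zero"):
        raise ValidationError(f"unknown degenerate-node policy {policy!r}")
    A = R_prev.values
    n = A.shape[0]
    C = centering_matrix(n)
    M = A @ C @ A
    M = (M + M.T) / 2.0
    d = np.diag(M).copy()
    degenerate = d <= DEGENERACY_EPS
    new_degenerate = frozenset(np.flatnonzero(degenerate).tolist())
    if degenerate.any() and policy == "error":
        idx = sorted(new_degenerate)
        raise DegenerateSignalError(
            f"constant row(s) {idx} in order-{R_prev.order} matrix "
            "(zero diagonal in R C R)",
            nodes=idx,
        )
    d_safe = np.where(degenerate, 1.0, d)
    # divide (rather than multiply by 1/sqrt) so closed-form cases like the
    # N = 2 step land exactly on +-1 in floating point
    R = M / np.sqrt(np.outer(d_safe, d_safe))
    if degenerate.any():
        R[degenerate, :] = 0.0
        R[:, degenerate] = 0.0
    return _finalize(
        R, order=R_prev.order + 1, degenerate=R_prev.degenerate_nodes | new_degenerate
    )


def pcn_sequence(
    ts: ROITimeSeries,
    n_max: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    stop_on_convergence: bool = True,
    policy: str = "error",
) -> BFNSequence:
    """Generate the BFN sequence R_1, R_2, ..., with convergence tracking.

    Iteration halts at ``n_max`` or, when ``stop_on_convergence`` is set,
    at the first order n with ``max|R_n - R_{n-1}| < tol``.  The attached
    :class:`ConvergenceReport` records the per-step deltas and a per-order
    binariness score.  Non-convergence within ``n_max`` is not an error.
    """
    if n_max < 1:
        raise ValidationError(f"n_max must be >= 1, got {n_max}")
    if not tol > 0:
        raise ValidationError(f"tol must be > 0, got {tol}")
    matrices = [pearson_bfn(ts, policy=policy)]
    binariness = [binariness_score(matrices[0].values)]
    deltas: list[float] = []
    converged = False
    n_converged: Optional[int] = None
    for order in range(2, n_max + 1):
        try:
            nxt = pcn_step(matrices[-1], policy=policy)
        except DegenerateSignalError as exc:
            raise DegenerateSignalError(
                f"degeneracy at order {order}: {exc}", nodes=exc.nodes, order=order
            ) from exc
        delta = float(np.abs(nxt.values - matrices[-1].values).max())
        deltas.append(delta)
        binariness.append(binariness_score(nxt.values))
        matrices.append(nxt)
        if delta < tol and not converged:
            converged = True
            n_converged = order
            if stop_on_convergence:
                break
    report = ConvergenceReport(
        converged=converged,
        n_converged=n_converged,
        step_deltas=tuple(deltas),
        binariness=tuple(binariness),
        tol=tol,
        max_iter=n_max,
    )
    return BFNSequence(matrices=tuple(matrices), report=report)


def converged_bfn(
    ts: ROITimeSeries,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    policy: str = "error",
) -> AdjacencyMatrix:
    """The empirically converged BFN (``PC^conv``): iterate until the
    max-abs change drops below ``tol``, capped at ``max_iter`` iterations.

    Returns the final matrix; its ``order`` is the stopping order.  If the
    cap is hit without convergence the last matrix is returned (the
    sequence's report, via :func:`pcn_sequence`, says whether it converged).
    """
    seq = pcn_sequence(
        ts, n_max=max_iter, tol=tol, stop_on_convergence=True, policy=policy
    )
    return seq.final
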