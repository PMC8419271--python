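"""Diagnostics for the PC^n matrix sequence.

Instruments the empirical observations about the iterated-correlation
sequence: the numerical rank is non-increasing along the sequence (the
rank of a product is at most the rank of each factor), only a small
number of off-diagonal entries flip sign late in the iteration, and the
map has exact fixed points — every rank-one sign matrix ``s s^T`` with
``s in {-1,+1}^N`` (both signs present) maps to itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .bfn import AdjacencyMatrix, BFNSequence, ValidationError, binariness_score, pcn_step

__all__ = [
    "DiagnosticsWarning",
    "SequenceDiagnostics",
    "rank_sequence",
    "sign_change_count",
    "fixed_point_residual",
    "compute_diagnostics",
]

#: Relative singular-value threshold used for numerical rank.
DEFAULT_RANK_RTOL = 1e-8


class DiagnosticsWarning(UserWarning):
    """An empirically-expected property of the sequence was violated."""


@dataclass(frozen=True)
class SequenceDiagnostics:
    """Per-order instrumentation of a BFN sequence.

    ``ranks`` and ``binariness`` have one entry per matrix,
    ``fixed_point_residual`` likewise, and ``sign_changes`` one entry per
    consecutive pair (one shorter).
    """

    ranks: tuple[int, ...]
    sign_changes: tuple[int, ...]
    fixed_point_residual: tuple[float, ...]
    binariness: tuple[float, ...]

    def __post_init__(self):
        n = len(self.ranks)
        if not (len(self.binariness) == n and len(self.fixed_point_residual) == n):
            raise ValidationError("diagnostics lists must share the sequence length")
        if len(self.sign_changes) != max(n - 1, 0):
            raise ValidationError("sign_changes must be one shorter than the sequence")

    def to_dict(self) -> dict:
        return {
            "ranks": list(self.ranks),
            "sign_changes": list(self.sign_changes),
            "fixed_point_residual": list(self.fixed_point_residual),
            "binariness": list(self.binariness),
        }


def rank_sequence(seq: BFNSequence, rel_tol: float = DEFAULT_RANK_RTOL) -> list[int]:
    """Numerical rank per order: singular values above ``rel_tol * sigma_max``.

    The sequence should be non-increasing; a violation raises a
    :class:`DiagnosticsWarning` naming the offending pair rather than an
    error (the monotonicity is a property of exact arithmetic).
    """
    if not 0 < rel_tol < 1:
        raise ValidationError(f"rel_tol must be in (0, 1), got {rel_tol}")
    ranks = []
    for mat in seq:
        s = np.linalg.svd(mat.values, compute_uv=False)
        ranks.append(int(np.sum(s > rel_tol * s[0])))
    for k in range(1, len(ranks)):
        if ranks[k] > ranks[k - 1]:
            warnings.warn(
                f"numerical rank increased from {ranks[k-1]} to {ranks[k]} "
                f"between orders {k} and {k + 1}",
                DiagnosticsWarning,
                stacklevel=2,
            )
    return ranks


def sign_change_count(seq: BFNSequence) -> list[int]:
    """Count strict sign flips of upper-triangle entries between consecutive
    orders (an exact zero counts as its own sign)."""
    if len(seq) < 2:
        raise ValidationError("sign_change_count needs at least 2 matrices")
    n = seq.n_rois
    iu = np.triu_indices(n, k=1)
    counts = []
    for prev, cur in zip(seq, seq.matrices[1:]):
        counts.append(int(np.sum(np.sign(prev.values[iu]) != np.sign(cur.values[iu]))))
    return counts


def fixed_point_residual(R: AdjacencyMatrix, policy: str = "error") -> float:
    """``max|pcn_step(R) - R|``; at most 1e-12 exactly when R is a fixed
    point of the iterated-correlation map."""
    return float(np.abs(pcn_step(R, policy=policy).values - R.values).max())


def compute_diagnostics(
    seq: BFNSequence, rel_tol: float = DEFAULT_RANK_RTOL, policy: str = "error"
) -> SequenceDiagnostics:
    """All per-order diagnostics for a sequence in one pass."""
    ranks = rank_sequence(seq, rel_tol=rel_tol)
    changes = sign_change_count(seq) if len(seq) >= 2 else []
    residuals = [fixed_point_residual(m, policy=policy) for m in seq]
    binariness = [binariness_score(m.values) for m in seq]
    return SequenceDiagnostics(
        ranks=tuple(ranks),
        sign_changes=tuple(changes),
        fixed_point_residual=tuple(residuals),
        binariness=tuple(binariness),
    )
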