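"""Model-style front end for PC^n network estimation.

``PCN`` wraps one scan's ROI time series; ``fit()`` runs the iterated
correlation map and returns a ``PCNResults`` object carrying the matrix
sequence, the convergence report, lazily-computed diagnostics, and a
``summary()`` table.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .bfn import (
    DEFAULT_MAX_ITER,
    DEFAULT_TOL,
    AdjacencyMatrix,
    BFNSequence,
    ROITimeSeries,
    pcn_sequence,
)
from .diagnostics import SequenceDiagnostics, compute_diagnostics

__all__ = ["PCN", "PCNResults"]


class PCN:
    """Iterated Pearson-correlation network model for one scan.

    Parameters
    ----------
    endog
        M x N array-like of ROI signals (rows = time points), an
        :class:`ROITimeSeries`, or a DataFrame whose columns are ROIs.
    scan_id, subject_id, label
        Metadata forwarded to the underlying time series.
    """

    def __init__(self, endog, scan_id: str = "scan", subject_id: str = "",
                 label: Optional[str] = None):
        if isinstance(endog, ROITimeSeries):
            self.data = endog
        elif isinstance(endog, pd.DataFrame):
            self.data = ROITimeSeries(
                values=endog.to_numpy(dtype=float),
                scan_id=scan_id,
                subject_id=subject_id,
                label=label,
                roi_names=tuple(str(c) for c in endog.columns),
            )
        else:
            self.data = ROITimeSeries(
                values=np.asarray(endog, dtype=float),
                scan_id=scan_id,
                subject_id=subject_id,
                label=label,
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "PCN":
        return cls(df, **kwargs)

    def fit(
        self,
        n_max: int = DEFAULT_MAX_ITER,
        tol: float = DEFAULT_TOL,
        stop_on_convergence: bool = True,
        policy: str = "error",
    ) -> "PCNResults":
        """Run the PC^n iteration and return results."""
        seq = pcn_sequence(
            self.data,
            n_max=n_max,
            tol=tol,
            stop_on_convergence=stop_on_convergence,
            policy=policy,
        )
        return PCNResults(self, seq, policy=policy)


class PCNResults:
    """Estimated BFN sequence with convergence report and diagnostics."""

    def __init__(self, model: PCN, sequence: BFNSequence, policy: str = "error"):
        self.model = model
        self.sequence = sequence
        self.report = sequence.report
        self.policy = policy
        self._diagnostics: Optional[SequenceDiagnostics] = None

    @property
    def params(self) -> np.ndarray:
        """The final (highest-order) adjacency matrix values."""
        return self.sequence.final.values

    @property
    def converged(self) -> bool:
        return self.report.converged

    @property
    def n_converged(self) -> Optional[int]:
        return self.report.n_converged

    def matrix(self, order) -> AdjacencyMatrix:
        """Adjacency matrix at an integer order or ``"conv"``."""
        return self.sequence.at_order(order)

    @property
    def diagnostics(self) -> SequenceDiagnostics:
        if self._diagnostics is None:
            self._diagnostics = compute_diagnostics(self.sequence, policy=self.policy)
        return self._diagnostics

    def summary(self) -> str:
        ts = self.model.data
        d = self.diagnostics
        rep = self.report
        head = (
            f"PC^n network estimation  scan={ts.scan_id!r}  "
            f"M={ts.n_timepoints} time points  N={ts.n_rois} ROIs\n"
            f"tol={rep.tol:g}  max_iter={rep.max_iter}  "
            + (
                f"converged at order {rep.n_converged}"
                if rep.converged
                else "not converged"
            )
        )
        lines = [head, "", f"{'order':>6} {'delta':>12} {'binariness':>11} {'rank':>5} {'sign flips':>11}"]
        for k, mat in enumerate(self.sequence):
            delta = f"{rep.step_deltas[k-1]:.3e}" if k >= 1 else "-"
            flips = str(d.sign_changes[k - 1]) if k >= 1 else "-"
            lines.append(
                f"{mat.order:>6} {delta:>12} {d.binariness[k]:>11.4f} "
                f"{d.ranks[k]:>5} {flips:>11}"
            )
        return "\n".join(lines)
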