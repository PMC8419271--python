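"""Synthetic ROI time series with controlled two-group covariance structure.

Generates Gaussian (optionally heavier-tailed) multivariate time series
whose population correlation matrix is block structured, with a configurable
set of edges whose correlation differs between the two groups — a planted
low-order class signal.  The default shape mirrors a resting-state cohort
with 116 AAL-style ROIs, 137 retained volumes per scan and 72 subjects per
group; an alternative preset mirrors an ICA-parcellated cohort with 100
ROIs and 1,200 volumes per session, four sessions per subject.

The generator produces no hemodynamic forward model and no scanner
artefacts (drift, spikes, motion); it emulates only the second-order
structure that the Pearson-based estimators consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy import signal as sp_signal

from .bfn import ROITimeSeries, ValidationError, pcn_sequence
from .classify import LabeledDataset, ScanRecord

__all__ = [
    "SyntheticSpec",
    "make_group_covariance",
    "simulate_scan",
    "simulate_dataset",
    "planted_edges",
    "preset_spec",
]

_SPD_EIG_FLOOR = 1e-8


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the two-group synthetic cohort.

    ``within_block_rho`` may be a single float (both groups) or a
    ``(negative, positive)`` pair.  ``differing_edges`` is a list of
    ``(i, j, delta_rho)`` applied to the positive group's correlation
    matrix; when ``None``, ``n_differing_edges`` between-block edges with
    shift ``differing_delta`` are drawn deterministically from ``seed``.
    ``scans_per_subject`` is an int or an inclusive ``(lo, hi)`` range
    sampled per subject.
    """

    n_rois: int = 116
    m_timepoints: int = 137
    n_subjects_per_group: int = 72
    scans_per_subject: Union[int, tuple[int, int]] = 1
    block_sizes: Optional[tuple[int, ...]] = None
    within_block_rho: Union[float, tuple[float, float]] = 0.3
    differing_edges: Optional[tuple[tuple[int, int, float], ...]] = None
    n_differing_edges: int = 30
    differing_delta: float = 0.3
    ar1_coef: float = 0.0
    noise_sd: float = 1.0
    heavy_tail_df: Optional[float] = None
    seed: int = 7
    class_names: tuple[str, str] = ("negative", "positive")

    def __post_init__(self):
        if self.n_rois < 2 or self.m_timepoints < 3:
            raise ValidationError("need n_rois >= 2 and m_timepoints >= 3")
        if self.n_subjects_per_group < 1:
            raise ValidationError("need at least one subject per group")
        if not 0.0 <= self.ar1_coef < 1.0:
            raise ValidationError(f"ar1_coef must be in [0, 1), got {self.ar1_coef}")
        if not self.noise_sd > 0:
            raise ValidationError(
                "noise_sd must be > 0 (zero noise would give rank-deficient columns)"
            )
        if self.heavy_tail_df is not None and self.heavy_tail_df <= 2:
            raise ValidationError("heavy_tail_df must exceed 2 for finite variance")
        for rho in self._rhos():
            if not abs(rho) < 1.0:
                raise ValidationError(f"|within_block_rho| must be < 1, got {rho}")
        if self.block_sizes is None:
            # default: blocks of 4 covering as many ROIs as possible
            object.__setattr__(
                self, "block_sizes", tuple([4] * (self.n_rois // 4))
            )
        if sum(self.block_sizes) > self.n_rois:
            raise ValidationError("block sizes exceed the ROI count")
        if isinstance(self.scans_per_subject, tuple):
            lo, hi = self.scans_per_subject
            if not 1 <= lo <= hi:
                raise ValidationError("scans_per_subject range must satisfy 1 <= lo <= hi")
        elif self.scans_per_subject < 1:
            raise ValidationError("scans_per_subject must be >= 1")

    def _rhos(self) -> tuple[float, float]:
        """(negative-group rho, positive-group rho)."""
        if isinstance(self.within_block_rho, tuple):
            return self.within_block_rho
        return (self.within_block_rho, self.within_block_rho)

    def resolved_differing_edges(self) -> tuple[tuple[int, int, float], ...]:
        if self.differing_edges is not None:
            return tuple(self.differing_edges)
        return planted_edges(
            self.n_rois,
            self.block_sizes,
            self.n_differing_edges,
            self.differing_delta,
            seed=self.seed,
        )


def planted_edges(
    n_rois: int,
    block_sizes: Sequence[int],
    n_edges: int,
    delta: float,
    seed: int = 0,
) -> tuple[tuple[int, int, float], ...]:
    """Draw ``n_edges`` distinct between-block edges to shift by ``delta``.

    Edges are between-block so the shift changes the positive group's
    correlation structure rather than just rescaling a block.
    """
    bounds = np.cumsum([0, *block_sizes])
    block_of = np.full(n_rois, -1)
    for b, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
        block_of[lo:hi] = b
    rng = np.random.default_rng([seed, 0xED6E])
    edges: set[tuple[int, int]] = set()
    guard = 0
    while len(edges) < n_edges:
        i, j = (int(v) for v in rng.integers(0, n_rois, 2))
        if i == j:
            continue
        i, j = min(i, j), max(i, j)
        if block_of[i] >= 0 and block_of[i] == block_of[j]:
            continue
        edges.add((i, j))
        guard += 1
        if guard > 100 * n_edges + 1000:
            raise ValidationError("could not place the requested differing edges")
    return tuple((i, j, float(delta)) for i, j in sorted(edges))


def _nearest_correlation_repair(S: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and rescale back to unit diagonal."""
    vals, vecs = np.linalg.eigh(S)
    vals = np.clip(vals, 1e-6, None)
    S = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(S))
    S = S / np.outer(d, d)
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return S


def make_group_covariance(spec: SyntheticSpec, group: str) -> np.ndarray:
    """Population correlation matrix for ``group`` ("negative"/"positive").

    Block-diagonal compound symmetry with the group's within-block rho;
    for the positive group the planted edge shifts are added.  A target
    that loses positive-definiteness is repaired to the nearest unit-
    diagonal SPD matrix (with a warning); an unrepairable target errors.
    """
    if group not in ("negative", "positive"):
        raise ValidationError(f"group must be 'negative' or 'positive', got {group!r}")
    rho = spec._rhos()[0 if group == "negative" else 1]
    S = np.eye(spec.n_rois)
    pos = 0
    for b in spec.block_sizes:
        S[pos : pos + b, pos : pos + b] = rho
        pos += b
    np.fill_diagonal(S, 1.0)
    if group == "positive":
        for i, j, delta in spec.resolved_differing_edges():
            target = S[i, j] + delta
            if not abs(target) < 1.0:
                raise ValidationError(
                    f"edge ({i},{j}) shift {delta} leaves correlation {target} outside (-1, 1)"
                )
            S[i, j] = S[j, i] = target
    min_eig = float(np.linalg.eigvalsh(S).min())
    if min_eig <= _SPD_EIG_FLOOR:
        warnings.warn(
            f"{group}-group correlation target not SPD (min eig {min_eig:.2e}); "
            "applying nearest-SPD repair",
            UserWarning,
            stacklevel=2,
        )
        S = _nearest_correlation_repair(S)
        if float(np.linalg.eigvalsh(S).min()) <= _SPD_EIG_FLOOR:
            raise ValidationError("correlation target not repairable to SPD")
    return S


def _scan_rng(spec: SyntheticSpec, group: str, subject_seed: int, scan_index: int):
    gidx = 0 if group == "negative" else 1
    return np.random.default_rng([spec.seed, gidx, int(subject_seed), scan_index])


def simulate_scan(
    spec: SyntheticSpec,
    group: str,
    subject_seed: int,
    scan_index: int = 0,
    subject_id: Optional[str] = None,
    cov: Optional[np.ndarray] = None,
) -> ROITimeSeries:
    """Draw one M x N scan with the group's covariance.

    Innovations are Gaussian (or scaled Student-t when ``heavy_tail_df``
    is set), colored by an AR(1) filter per ROI when ``ar1_coef`` > 0,
    then re-standardized per column.  Fully deterministic under
    ``(spec.seed, group, subject_seed, scan_index)``.
    """
    if cov is None:
        cov = make_group_covariance(spec, group)
    L = np.linalg.cholesky(cov)
    rng = _scan_rng(spec, group, subject_seed, scan_index)
    Z = rng.standard_normal((spec.m_timepoints, spec.n_rois))
    if spec.heavy_tail_df is not None:
        df = spec.heavy_tail_df
        # per-timepoint chi-square mixing -> multivariate-t rows, unit variance
        g = rng.chisquare(df, size=(spec.m_timepoints, 1)) / df
        Z = Z / np.sqrt(g) * np.sqrt((df - 2.0) / df)
    X = (Z @ L.T) * spec.noise_sd
    if spec.ar1_coef > 0:
        X = sp_signal.lfilter([1.0], [1.0, -spec.ar1_coef], X, axis=0)
    # re-standardize so downstream estimators see comparable scales
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd <= 0):
        raise ValidationError("degenerate simulated column (zero variance)")
    X = X / sd
    subj = subject_id or f"{group[:3]}-{subject_seed:04d}"
    label = spec.class_names[0 if group == "negative" else 1]
    return ROITimeSeries(
        values=X,
        scan_id=f"{subj}-s{scan_index}",
        subject_id=subj,
        label=label,
    )


def _scan_counts(spec: SyntheticSpec, n_subjects: int, rng) -> list[int]:
    if isinstance(spec.scans_per_subject, tuple):
        lo, hi = spec.scans_per_subject
        return [int(rng.integers(lo, hi + 1)) for _ in range(n_subjects)]
    return [int(spec.scans_per_subject)] * n_subjects


def simulate_dataset(
    spec: SyntheticSpec,
    orders: Sequence = (1, "conv"),
    tol: float = 1e-6,
    max_iter: int = 30,
) -> LabeledDataset:
    """Balanced two-group dataset with BFN matrices at the requested orders.

    Each subject contributes ``scans_per_subject`` scans; per scan the
    PC^n sequence is run (stopping at convergence or ``max_iter``) and the
    matrices at the requested orders are attached.  Integer orders beyond
    the stopping order resolve to the final (converged) matrix.
    """
    int_orders = [o for o in orders if o != "conv"]
    n_max = max([max_iter if "conv" in orders else 1, *(int(o) for o in int_orders), 1])
    scans = []
    count_rng = np.random.default_rng([spec.seed, 0xC0])
    for group in ("negative", "positive"):
        cov = make_group_covariance(spec, group)
        counts = _scan_counts(spec, spec.n_subjects_per_group, count_rng)
        for s in range(spec.n_subjects_per_group):
            subj = f"{group[:3]}-{s:04d}"
            for scan_index in range(counts[s]):
                ts = simulate_scan(
                    spec, group, subject_seed=s, scan_index=scan_index,
                    subject_id=subj, cov=cov,
                )
                seq = pcn_sequence(
                    ts, n_max=n_max, tol=tol, stop_on_convergence=True
                )
                matrices = {o: seq.at_order(o) for o in orders}
                scans.append(
                    ScanRecord(matrices=matrices, subject_id=subj, label=ts.label)
                )
    return LabeledDataset(scans=tuple(scans), positive_class_name=spec.class_names[1])


def preset_spec(name: str, seed: int = 7) -> SyntheticSpec:
    """Named study-shape presets.

    ``"adni"``: 116 ROIs x 137 volumes, 72 subjects per group with 1-3
    scans each (mixed-scan cohort).  ``"hcp"``: 100 ROIs x 1,200 volumes,
    four sessions per subject, 25 subjects per group.
    """
    if name == "adni":
        return SyntheticSpec(seed=seed, scans_per_subject=(1, 3))
    if name == "hcp":
        return SyntheticSpec(
            n_rois=100,
            m_timepoints=1200,
            n_subjects_per_group=25,
            scans_per_subject=4,
            seed=seed,
        )
    raise ValidationError(f"unknown preset {name!r} (expected 'adni' or 'hcp')")
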