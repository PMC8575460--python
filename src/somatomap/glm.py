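"""Blocked-design GLM: design matrices, OLS fits, contrasts, percent signal change.

Five finger regressors (double-gamma HRF-convolved boxcars) plus their
temporal derivatives, a discrete-cosine high-pass basis (100 s cutoff by
default, included as nuisance columns rather than applied as a pre-filter)
and an intercept.  Fits are plain OLS; run-level contrasts are averaged with
equal weights across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from .design import REST, DesignSpec, RunDescriptor, condition_regressors, validate_blocked_order

HIGHPASS_CUTOFF_BLOCKED = 100.0
HIGHPASS_CUTOFF_TRAVELWAVE = 90.0


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # (n_volumes, n_regressors)
    labels: List[str]
    condition_columns: List[int]  # the 5 finger columns, in finger order

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]


@dataclass
class GLMResult:
    betas: np.ndarray  # (n_voxels, n_regressors)
    residuals: np.ndarray  # (n_voxels, n_volumes)
    dm: DesignMatrix
    error_variance: np.ndarray  # (n_voxels,)

    def contrast(self, weights: Sequence[float]) -> np.ndarray:
        w = np.asarray(weights, dtype=float)
        if w.size != self.betas.shape[1]:
            raise ValueError("contrast length must match regressor count")
        return self.betas @ w

    def finger_vs_rest(self, finger: int) -> np.ndarray:
        """Finger betas are relative to the implicit rest baseline."""
        w = np.zeros(self.betas.shape[1])
        w[self.dm.condition_columns[finger - 1]] = 1.0
        return self.contrast(w)

    def all_vs_rest(self) -> np.ndarray:
        w = np.zeros(self.betas.shape[1])
        w[self.dm.condition_columns] = 1.0 / 5.0
        return self.contrast(w)

    def condition_betas(self) -> np.ndarray:
        """(n_voxels, 5) finger-versus-rest estimates, finger order 1..5."""
        return self.betas[:, self.dm.condition_columns]


@dataclass
class PSCResult:
    psc: float
    roi_label: str
    n_voxels: int
    per_run: List[float]


def dct_highpass_basis(n_volumes: int, tr: float, cutoff: float) -> np.ndarray:
    """Discrete cosine drift columns for periods longer than ``cutoff`` seconds."""
    duration = n_volumes * tr
    k_max = int(np.floor(2.0 * duration / cutoff))
    t = (np.arange(n_volumes) + 0.5) / n_volumes
    cols = [np.cos(np.pi * k * t) for k in range(1, k_max + 1)]
    if not cols:
        return np.empty((n_volumes, 0))
    basis = np.column_stack(cols)
    return basis / np.abs(basis).max(axis=0)


def build_design_matrix(
    design: DesignSpec,
    run: RunDescriptor,
    hrf_kind: str = "double_gamma",
    highpass_cutoff: float = HIGHPASS_CUTOFF_BLOCKED,
) -> DesignMatrix:
    """Design matrix for one blocked run; rejects invalid condition orders."""
    if run.kind != "blocked":
        raise ValueError("design matrices are built for blocked runs")
    validate_blocked_order(design, run.order)
    conds = condition_regressors(design, run, hrf_kind)
    derivs = condition_regressors(design, run, hrf_kind, derivative=True)
    n_vol = conds.shape[0]
    drift = dct_highpass_basis(n_vol, design.tr_seconds, highpass_cutoff)
    intercept = np.ones((n_vol, 1))
    mat = np.column_stack([conds, derivs, drift, intercept])
    labels = (
        [f"finger{i}" for i in range(1, 6)]
        + [f"finger{i}_deriv" for i in range(1, 6)]
        + [f"dct{k}" for k in range(1, drift.shape[1] + 1)]
        + ["intercept"]
    )
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        raise ValueError(f"design matrix rank deficient ({rank} < {mat.shape[1]})")
    return DesignMatrix(matrix=mat, labels=labels, condition_columns=list(range(5)))


def fit_glm(run_matrix: np.ndarray, dm: DesignMatrix) -> GLMResult:
    """Voxel-wise OLS fit of one run against a design matrix."""
    if run_matrix.ndim != 2:
        raise ValueError("run matrix must be voxels x time")
    if run_matrix.shape[1] != dm.n_volumes:
        raise ValueError(
            f"time dimension mismatch: data {run_matrix.shape[1]}, design {dm.n_volumes}"
        )
    x = dm.matrix
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name offending columns: those whose removal restores full rank
        bad = [
            dm.labels[j]
            for j in range(x.shape[1])
            if np.linalg.matrix_rank(np.delete(x, j, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design; offending columns: {bad}")
    betas, *_ = np.linalg.lstsq(x, run_matrix.T, rcond=None)
    betas = betas.T
    resid = run_matrix - betas @ x.T
    dof = max(x.shape[0] - x.shape[1], 1)
    return GLMResult(
        betas=betas,
        residuals=resid,
        dm=dm,
        error_variance=(resid**2).sum(axis=1) / dof,
    )


def percent_signal_change(
    results: Sequence[GLMResult],
    roi_mask: np.ndarray,
    contrast: str = "all_vs_rest",
    roi_label: str = "hand_S1",
    baseline: Optional[float] = None,
) -> PSCResult:
    """Mean contrast estimate over an ROI, averaged across runs, in % units.

    Simulated matrices are already expressed in percent signal change around a
    zero baseline, so with unit-peak regressors the contrast estimate *is* the
    percent signal change and no further scaling applies.  When ``baseline``
    (the raw mean signal) is given, estimates are scaled by 100 / baseline
    instead (plain mean-signal scaling).
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.sum() == 0:
        raise ValueError("empty ROI")
    per_run = []
    for res in results:
        if contrast == "all_vs_rest":
            c = res.all_vs_rest()
        elif contrast.startswith("finger"):
            c = res.finger_vs_rest(int(contrast.replace("finger", "")))
        else:
            raise ValueError(f"unknown contrast {contrast!r}")
        val = float(c[roi_mask].mean())
        if baseline is not None:
            if baseline <= 0:
                raise ValueError("baseline must be positive")
            val *= 100.0 / baseline
        per_run.append(val)
    return PSCResult(
        psc=float(np.mean(per_run)),
        roi_label=roi_label,
        n_voxels=int(roi_mask.sum()),
        per_run=per_run,
    )


def fit_subject_runs(
    design: DesignSpec,
    runs: Sequence,
    hrf_kind: str = "double_gamma",
) -> List[GLMResult]:
    """Fit each (RunDescriptor, matrix) blocked run of one subject."""
    out = []
    for run, mat in runs:
        dm = build_design_matrix(design, run, hrf_kind)
        out.append(fit_glm(mat, dm))
    return out
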