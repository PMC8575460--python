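"""Crossnobis representational similarity analysis.

Run-wise condition patterns are multivariately noise-normalised using a
shrinkage estimate of the residual voxel covariance, and the cross-validated
squared Mahalanobis distance is averaged over all unordered run pairs.  The
5 x 5 RDM feeds separability (mean of the 10 unique off-diagonals),
typicality (Spearman correlation with a canonical RDM, Fisher r-to-z) and a
classical-MDS + Procrustes group visualisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _stats
from scipy.linalg import orthogonal_procrustes

from .synth import GroundTruthMap, response_profiles

N_CONDITIONS = 5
N_UNIQUE_PAIRS = 10
_TRIU = np.triu_indices(N_CONDITIONS, k=1)


@dataclass
class NoiseModel:
    covariance: np.ndarray  # (P, P) shrunk covariance
    whitening: np.ndarray  # W with W S W' = I
    shrinkage: float


@dataclass
class RDM:
    matrix: np.ndarray  # (5, 5) symmetric, zero diagonal
    condition_labels: Tuple[str, ...] = tuple(f"finger{i}" for i in range(1, 6))

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (N_CONDITIONS, N_CONDITIONS):
            raise ValueError("RDM must be 5 x 5")
        if not np.allclose(m, m.T):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("RDM diagonal must be zero")
        self.matrix = m

    def unique_values(self) -> np.ndarray:
        """The 10 unique off-diagonal entries (upper triangle, row-major)."""
        return self.matrix[_TRIU]


@dataclass(frozen=True)
class TypicalityScore:
    rho: float
    fisher_z: float
    defined: bool = True


@dataclass
class MDSConfiguration:
    coords: np.ndarray  # (n_subjects, 5, 2) aligned coordinates
    mean: np.ndarray  # (5, 2)
    se: np.ndarray  # (5, 2) between-subject standard error
    truncated_mass: np.ndarray  # per subject, |negative eigenvalue| fraction


def estimate_noise_model(
    residuals_per_run: Sequence[np.ndarray], shrinkage: float = 0.1
) -> NoiseModel:
    """Pooled run-wise residual covariance, shrunk toward its diagonal.

    ``residuals_per_run``: arrays of shape (n_timepoints, n_voxels).  The
    whitening transform is the inverse symmetric square root of the shrunk
    covariance.
    """
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must lie in [0, 1]")
    mats = [np.asarray(r, dtype=float) for r in residuals_per_run]
    if any(r.shape[0] < 2 for r in mats):
        raise ValueError("need more than one residual time point per run")
    p = mats[0].shape[1]
    cov = np.zeros((p, p))
    for r in mats:
        rc = r - r.mean(axis=0, keepdims=True)
        cov += rc.T @ rc / (r.shape[0] - 1)
    cov /= len(mats)
    shrunk = (1.0 - shrinkage) * cov + shrinkage * np.diag(np.diag(cov))
    vals, vecs = np.linalg.eigh(shrunk)
    if vals.min() <= 1e-12 * max(vals.max(), 1.0):
        raise ValueError(
            "covariance singular after shrinkage; raise the shrinkage weight "
            "(more voxels than residual time points?)"
        )
    whitening = vecs @ np.diag(vals**-0.5) @ vecs.T
    return NoiseModel(covariance=shrunk, whitening=whitening, shrinkage=shrinkage)


def diagonal_noise_model(residuals_per_run: Sequence[np.ndarray]) -> NoiseModel:
    """Univariate (per-voxel) variant: whitening by each voxel's residual SD."""
    return estimate_noise_model(residuals_per_run, shrinkage=1.0)


def crossnobis_distances(
    betas: np.ndarray, noise: Optional[NoiseModel] = None
) -> np.ndarray:
    """Cross-validated squared Mahalanobis distances between condition patterns.

    ``betas`` has shape (n_runs, n_conditions, n_voxels).  With prewhitened
    patterns u, the distance for pair (i, j) is the average over all unordered
    run pairs (r, s) of (u_ir - u_jr) . (u_is - u_js) / P.  Cross-validation
    makes the estimate unbiased: zero in expectation for identical true
    patterns, and individual estimates may be negative.  Returns the full
    symmetric (n_conditions, n_conditions) matrix.
    """
    b = np.asarray(betas, dtype=float)
    if b.ndim != 3:
        raise ValueError("betas must be (runs, conditions, voxels)")
    n_runs, n_cond, p = b.shape
    if n_runs < 2:
        raise ValueError("crossnobis needs at least 2 runs for cross-validation")
    u = b @ noise.whitening.T if noise is not None else b
    iu = np.triu_indices(n_cond, k=1)
    # pairwise condition differences per run: (n_runs, n_pairs, P)
    diffs = u[:, iu[0], :] - u[:, iu[1], :]
    # mean over unordered run pairs of cross-products
    total = np.zeros(len(iu[0]))
    n_pairs = 0
    for r in range(n_runs):
        for s in range(r + 1, n_runs):
            total += np.einsum("ij,ij->i", diffs[r], diffs[s])
            n_pairs += 1
    d = total / (n_pairs * p)
    mat = np.zeros((n_cond, n_cond))
    mat[iu] = d
    mat += mat.T
    return mat


def crossnobis(betas: np.ndarray, noise: Optional[NoiseModel] = None) -> RDM:
    """Five-condition crossnobis distances assembled into an RDM."""
    b = np.asarray(betas, dtype=float)
    if b.ndim != 3 or b.shape[1] != N_CONDITIONS:
        raise ValueError(f"expected (runs, {N_CONDITIONS} conditions, voxels) betas")
    return RDM(matrix=crossnobis_distances(b, noise))


def separability(rdm: RDM) -> float:
    """Mean of the 10 unique off-diagonal distances."""
    return float(rdm.unique_values().mean())


def csf_control(
    betas_hand: np.ndarray,
    noise_hand: Optional[NoiseModel],
    betas_csf: np.ndarray,
    noise_csf: Optional[NoiseModel],
) -> Tuple[float, float]:
    """Separability in the hand ROI versus a CSF control ROI."""
    if betas_hand.shape[-1] == 0 or betas_csf.shape[-1] == 0:
        raise ValueError("empty ROI")
    return (
        separability(crossnobis(betas_hand, noise_hand)),
        separability(crossnobis(betas_csf, noise_csf)),
    )


def typicality(rdm: RDM, canonical: RDM) -> TypicalityScore:
    """Spearman correlation of the subject's 10 unique distances with canonical.

    Fisher z is stored for inference; raw rho is retained for display.  A
    zero-variance rank vector makes the score undefined.
    """
    a = rdm.unique_values()
    b = canonical.unique_values()
    if np.all(a == a[0]) or np.all(b == b[0]):
        return TypicalityScore(float("nan"), float("nan"), defined=False)
    rho, _ = _stats.spearmanr(a, b)
    rho = float(rho)
    z = float(np.arctanh(np.clip(rho, -1 + 1e-12, 1 - 1e-12)))
    return TypicalityScore(rho=rho, fisher_z=z)


def canonical_rdm_from_truth(truth: GroundTruthMap) -> RDM:
    """Noise-free canonical RDM from a ground-truth template (delta = 0).

    Squared Euclidean pattern distances per voxel over the hand ROI; serves as
    the default canonical reference in place of an external normative cohort.
    """
    profiles = response_profiles(truth, delta=0.0)[truth.hand_mask]  # (P, 5)
    p = profiles.shape[0]
    mat = np.zeros((N_CONDITIONS, N_CONDITIONS))
    for i in range(N_CONDITIONS):
        for j in range(i + 1, N_CONDITIONS):
            d = profiles[:, i] - profiles[:, j]
            mat[i, j] = mat[j, i] = float(d @ d) / p
    return RDM(matrix=mat)


def load_rdm_csv(path) -> RDM:
    """Read a 5 x 5 canonical RDM from a delimited table (no header/index)."""
    df = pd.read_csv(path, header=None)
    return RDM(matrix=df.to_numpy(dtype=float))


def save_rdm_csv(rdm: RDM, path) -> None:
    pd.DataFrame(rdm.matrix).to_csv(path, header=False, index=False)


def classical_mds(rdm: RDM, n_dims: int = 2) -> Tuple[np.ndarray, float]:
    """Classical (Torgerson) MDS of a squared-distance matrix.

    Crossnobis RDMs are squared distances and may contain negative entries;
    negative Gram eigenvalues are truncated and their relative mass returned.
    """
    d2 = rdm.matrix
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(gram)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    total = np.abs(vals).sum()
    trunc = float(np.abs(vals[vals < 0]).sum() / total) if total > 0 else 0.0
    top = np.clip(vals[:n_dims], 0, None)
    coords = vecs[:, :n_dims] * np.sqrt(top)
    return coords, trunc


def _align(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Orthogonal Procrustes (rotation/reflection, no scaling) after centring."""
    sc = source - source.mean(axis=0)
    tc = target - target.mean(axis=0)
    rot, _ = orthogonal_procrustes(sc, tc)
    return sc @ rot


def mds_procrustes(
    rdms: Sequence[RDM],
    reference: Optional[np.ndarray] = None,
    n_iter: int = 10,
    tol: float = 1e-8,
) -> MDSConfiguration:
    """Per-subject classical MDS with generalised Procrustes group alignment.

    Configurations are iteratively aligned (rotation/reflection only) to the
    evolving group mean, or to an explicit ``reference`` configuration.
    """
    if len(rdms) == 0:
        raise ValueError("need at least one RDM")
    raw = []
    trunc = []
    for r in rdms:
        c, t = classical_mds(r)
        raw.append(c)
        trunc.append(t)
    coords = np.stack(raw)
    if reference is not None:
        aligned = np.stack([_align(c, reference) for c in coords])
    else:
        target = coords[0] - coords[0].mean(axis=0)
        for _ in range(n_iter):
            aligned = np.stack([_align(c, target) for c in coords])
            new_target = aligned.mean(axis=0)
            if np.linalg.norm(new_target - target) < tol:
                target = new_target
                break
            target = new_target
        aligned = np.stack([_align(c, target) for c in coords])
    mean = aligned.mean(axis=0)
    se = aligned.std(axis=0, ddof=1) / np.sqrt(len(rdms)) if len(rdms) > 1 else np.zeros_like(mean)
    return MDSConfiguration(
        coords=aligned, mean=mean, se=se, truncated_mass=np.asarray(trunc)
    )


def subject_rdm(
    glm_results: Sequence, roi_mask: np.ndarray, shrinkage: float = 0.1,
    spatial_whitening: bool = True,
) -> RDM:
    """RDM for one subject from run-wise GLM results restricted to an ROI."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.sum() == 0:
        raise ValueError("empty ROI")
    betas = np.stack([res.condition_betas()[roi_mask].T for res in glm_results])
    residuals = [res.residuals[roi_mask].T for res in glm_results]
    if spatial_whitening:
        noise = estimate_noise_model(residuals, shrinkage)
    else:
        noise = diagonal_noise_model(residuals)
    return crossnobis(betas, noise)
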