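"""Phase-encoded (travelling-wave) lag analysis.

A bank of 25 circularly lag-shifted reference models (HRF-convolved 10 s
on / 40 s off boxcar, one shift per TR over the 50 s cycle) is correlated
with every voxel's time course.  Lag-wise Fisher z values are grouped into
five consecutive lag bins - one per finger - and combined across runs into
winner-take-all finger and lag maps, with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace
from typing import List, Optional, Sequence

import numpy as np
from scipy import stats as _stats

from .design import FINE_DT, DesignSpec, FORWARD_SEQUENCE
from .hrf import make_hrf
from .stats import bh_fdr

_Z_CLIP = 1.0 - 1e-12


@dataclass
class ReferenceModelBank:
    """25 standardised lag regressors tiled over the run's cycle grid."""

    models: np.ndarray  # (n_lags, n_cycle_volumes)
    design: DesignSpec
    hrf_kind: str = "gamma"

    @property
    def n_lags(self) -> int:
        return self.models.shape[0]

    @property
    def pad_volumes(self) -> int:
        return self.design.pad_volumes

    @property
    def n_volumes(self) -> int:
        return self.pad_volumes + self.models.shape[1]


@dataclass
class LagCorrelationMap:
    """Per-voxel Fisher z for each of the 25 lags, for one run."""

    z: np.ndarray  # (n_voxels, n_lags)
    direction: str  # "forward" | "backward"
    sequence: tuple

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "backward"):
            raise ValueError(f"bad direction {self.direction!r}")


@dataclass
class FingerSelectivityMap:
    finger_z: np.ndarray  # (n_voxels, 5)
    winner_finger: np.ndarray  # int in 1..5
    winner_z: np.ndarray
    tie_flag: np.ndarray
    significant: Optional[np.ndarray] = None
    p_values: Optional[np.ndarray] = None

    @property
    def n_voxels(self) -> int:
        return self.finger_z.shape[0]


@dataclass
class LagWinnerMap:
    combined_z: np.ndarray  # (n_voxels, n_lags)
    winner_lag: np.ndarray  # int in 0..24
    winner_z: np.ndarray
    tie_flag: np.ndarray


@dataclass
class ProbabilityMap:
    counts: np.ndarray  # (n_voxels, 5) subject counts
    group: str
    n_subjects: int


def build_reference_models(
    design: DesignSpec, hrf_kind: str = "gamma", dt: float = FINE_DT
) -> ReferenceModelBank:
    """Build the lag-shifted reference bank.

    The base model is the steady-state (circular) response of one 50 s cycle:
    a 10 s-on boxcar circularly convolved with the HRF, sampled at the TR.
    Lag k is the base circularly shifted by k volumes; each model is tiled
    across the run's cycles and standardised to zero mean, unit variance.
    The baseline pad lies outside the cycle grid and is not modelled.
    """
    n_lags = design.n_lags
    cyc_fine = int(round(design.tw_cycle_seconds / dt))
    box = np.zeros(cyc_fine)
    box[: int(round(design.tw_block_on / dt))] = 1.0
    kern = make_hrf(hrf_kind, dt)
    full = np.convolve(box, kern) * dt
    circ = np.zeros(cyc_fine)
    for start in range(0, len(full), cyc_fine):
        seg = full[start : start + cyc_fine]
        circ[: len(seg)] += seg
    step = int(round(design.tr_seconds / dt))
    base = circ[::step][:n_lags]
    models = np.empty((n_lags, design.tw_cycle_volumes))
    for k in range(n_lags):
        lagged = np.roll(base, k)
        tiled = np.tile(lagged, design.tw_cycles_per_run)
        models[k] = (tiled - tiled.mean()) / tiled.std()
    return ReferenceModelBank(models=models, design=design, hrf_kind=hrf_kind)


def crosscorrelate(
    run_matrix: np.ndarray, bank: ReferenceModelBank, run_direction: str = "forward",
    sequence: tuple = FORWARD_SEQUENCE,
) -> LagCorrelationMap:
    """Pearson-correlate each voxel with every lag model; Fisher r-to-z.

    The initial baseline-pad volumes are dropped before correlating.
    Constant time courses get z = 0 by convention.
    """
    if run_matrix.ndim != 2:
        raise ValueError("run matrix must be 2-D (voxels x time)")
    if run_matrix.shape[1] != bank.n_volumes:
        raise ValueError(
            f"run has {run_matrix.shape[1]} volumes, bank expects {bank.n_volumes}"
        )
    data = run_matrix[:, bank.pad_volumes :]
    dc = data - data.mean(axis=1, keepdims=True)
    sd = dc.std(axis=1)
    t = data.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (dc @ bank.models.T) / (t * sd[:, None])  # models are z-scored
    r[sd == 0] = 0.0
    z = np.arctanh(np.clip(r, -_Z_CLIP, _Z_CLIP))
    return LagCorrelationMap(z=z, direction=run_direction, sequence=tuple(sequence))


def correlate_runs(
    runs: Sequence, bank: ReferenceModelBank
) -> List[LagCorrelationMap]:
    """Convenience: crosscorrelate a list of (RunDescriptor, matrix) pairs."""
    out = []
    for run, mat in runs:
        out.append(crosscorrelate(mat, bank, run.direction, tuple(run.sequence)))
    return out


def reversed_lag_index(n_lags: int = 25) -> np.ndarray:
    """Lag-reversal permutation for backward runs.

    Reversing the cue cycle swaps block positions p and 4 - p, i.e. lag
    5p <-> 20 - 5p (for 25 lags), so lag k of a backward run corresponds to
    forward lag (n_lags - n_lags/5 - k) mod n_lags.  On noiseless data this
    maps a backward run's lag profile exactly onto the forward profile.
    """
    shift = n_lags - n_lags // 5
    return (shift - np.arange(n_lags)) % n_lags


def default_lag_assignment(n_lags: int = 25) -> List[np.ndarray]:
    """Partition lags into 5 circular groups of 5 centred on each cue position.

    The reference model already carries the HRF lag, so the response of the
    finger cued at cycle position p peaks exactly at lag 5p; the group for
    position p is {5p-2 .. 5p+2} (mod n_lags).  Centred windows keep the
    assignment symmetric around the peak, which is what makes forward and
    backward runs agree voxel-by-voxel on noiseless data.
    """
    if n_lags % 5:
        raise ValueError("lag count must be divisible by 5")
    w = n_lags // 5
    half = w // 2
    return [(np.arange(i * w - half, i * w - half + w)) % n_lags for i in range(5)]


def combine_runs_to_fingers(
    maps: Sequence[LagCorrelationMap],
    lag_assignment: Optional[Sequence[np.ndarray]] = None,
) -> FingerSelectivityMap:
    """Average lag-group z per finger within runs, then across runs; winner-take-all.

    For each run, the lag group at cycle position p is assigned to the finger
    cued at position p of that run's sequence, so backward runs' labels are
    remapped through the reversed cue order before averaging.  Ties resolve to
    the lowest finger index with ``tie_flag`` set.
    """
    if len(maps) == 0:
        raise ValueError("at least one run required")
    groups = list(lag_assignment) if lag_assignment is not None else default_lag_assignment(
        maps[0].z.shape[1]
    )
    if len(groups) != 5:
        raise ValueError("lag assignment must define 5 finger groups")
    n_lags = maps[0].z.shape[1]
    finger_z = np.zeros((maps[0].z.shape[0], 5))
    for m in maps:
        if m.z.shape != maps[0].z.shape:
            raise ValueError("all runs must share one voxel grid and lag count")
        if m.direction == "backward":
            z = m.z[:, reversed_lag_index(n_lags)]
            seq = tuple(reversed(m.sequence))
        else:
            z, seq = m.z, m.sequence
        for finger in range(1, 6):
            pos = seq.index(finger)
            finger_z[:, finger - 1] += z[:, groups[pos]].mean(axis=1)
    finger_z /= len(maps)
    winner = np.argmax(finger_z, axis=1)
    winner_z = finger_z[np.arange(len(winner)), winner]
    ties = (finger_z == winner_z[:, None]).sum(axis=1) > 1
    return FingerSelectivityMap(
        finger_z=finger_z,
        winner_finger=winner + 1,
        winner_z=winner_z,
        tie_flag=ties,
    )


def lag_winner_map(
    forward_maps: Sequence[LagCorrelationMap], backward_maps: Sequence[LagCorrelationMap]
) -> LagWinnerMap:
    """Combine forward and lag-reversed backward z profiles; winner-take-all lag.

    Backward profiles are remapped through ``reversed_lag_index`` so a voxel's
    phase lands in the same lag bin in both directions.
    """
    if not forward_maps or not backward_maps:
        raise ValueError("need at least one forward and one backward run")
    rev = reversed_lag_index(forward_maps[0].z.shape[1])
    stack = [m.z for m in forward_maps] + [m.z[:, rev] for m in backward_maps]
    combined = np.mean(stack, axis=0)
    winner = np.argmax(combined, axis=1)
    wz = combined[np.arange(len(winner)), winner]
    ties = (combined == wz[:, None]).sum(axis=1) > 1
    return LagWinnerMap(combined_z=combined, winner_lag=winner, winner_z=wz, tie_flag=ties)


def z_to_p(z: np.ndarray, n_eff: float) -> np.ndarray:
    """Two-sided normal p for Fisher z with nominal SD 1/sqrt(n_eff - 3)."""
    if n_eff <= 3:
        raise ValueError("n_eff must exceed 3")
    se = 1.0 / np.sqrt(n_eff - 3.0)
    return 2.0 * _stats.norm.sf(np.abs(z) / se)


def fdr_threshold(
    fmap: FingerSelectivityMap,
    q: float = 0.05,
    n_eff: float = 175.0,
    mask: Optional[np.ndarray] = None,
) -> FingerSelectivityMap:
    """Benjamini-Hochberg threshold on the winner z values within ``mask``."""
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    if mask is None:
        mask = np.ones(fmap.n_voxels, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty mask")
    p = np.ones(fmap.n_voxels)
    p[mask] = z_to_p(fmap.winner_z[mask], n_eff)
    sig = np.zeros(fmap.n_voxels, dtype=bool)
    reject, _ = bh_fdr(p[mask], q)
    sig[mask] = reject
    return _dc_replace(fmap, significant=sig, p_values=p)


def probability_map(
    maps: Sequence[FingerSelectivityMap], group: str = ""
) -> ProbabilityMap:
    """Per finger/voxel count of subjects whose thresholded map picks that finger."""
    if not maps:
        raise ValueError("no maps given")
    n_vox = maps[0].n_voxels
    counts = np.zeros((n_vox, 5), dtype=int)
    for m in maps:
        if m.n_voxels != n_vox:
            raise ValueError("maps must share one grid")
        if m.significant is None:
            raise ValueError("maps must be thresholded (run fdr_threshold first)")
        for f in range(1, 6):
            counts[:, f - 1] += (m.significant & (m.winner_finger == f)).astype(int)
    return ProbabilityMap(counts=counts, group=group, n_subjects=len(maps))
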