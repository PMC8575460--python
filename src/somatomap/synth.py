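"""Synthetic BOLD cohort generator with known somatotopic ground truth.

Voxels inside a hand-area slab carry Gaussian finger tuning arranged as a
monotone thumb-to-little gradient along the first lattice axis.  A
deterioration parameter ``delta`` in [0, 1] mixes each voxel's tuned response
profile toward the finger-uniform mean profile (weight ``delta``) and scatters
preferred fingers, degrading somatotopic structure while leaving the mean
all-fingers response untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import lfilter

from . import design as _design
from .design import (
    DesignSpec,
    RunDescriptor,
    condition_regressors,
    default_travelwave_runs,
    make_blocked_orders,
)

GROUPS = ("control", "sci", "one_hander")

ROI_BACKGROUND = 0
ROI_HAND = 1
ROI_CSF = 2

# delta = years_since_sci / DETERIORATION_YEARS_SCALE, clipped to [0, 1]
DETERIORATION_YEARS_SCALE = 35.0


@dataclass(frozen=True)
class NoiseParams:
    sigma: float = 0.5
    ar_rho: float = 0.0


@dataclass
class GroundTruthMap:
    """Per-voxel tuning ground truth on a flat voxel index over ``grid_shape``."""

    grid_shape: Tuple[int, int, int]
    preferred_finger: np.ndarray  # int, 0 where untuned
    tuning_width: np.ndarray  # float, finger units
    amplitude: np.ndarray  # float, % signal
    roi_labels: np.ndarray  # int codes: background / hand / CSF

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))

    @property
    def hand_mask(self) -> np.ndarray:
        return self.roi_labels == ROI_HAND

    @property
    def csf_mask(self) -> np.ndarray:
        return self.roi_labels == ROI_CSF

    @property
    def tuned_mask(self) -> np.ndarray:
        return self.preferred_finger > 0


@dataclass(frozen=True)
class SubjectSpec:
    subject_id: str
    group: str
    deterioration: float
    rng_seed: int
    years_since_sci: float = float("nan")
    motor_score: float = float("nan")
    sensory_score: float = float("nan")
    tissue_bridges: float = float("nan")
    cord_area: float = float("nan")

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if not 0.0 <= self.deterioration <= 1.0:
            raise ValueError("deterioration must lie in [0, 1]")


@dataclass(frozen=True)
class CohortConfig:
    """Tunable knobs of the generator; defaults mirror the simulated study."""

    design: DesignSpec = field(default_factory=DesignSpec)
    grid_shape: Tuple[int, int, int] = (20, 20, 10)
    amplitude: float = 1.0
    tuning_width: float = 1.0
    noise: NoiseParams = field(default_factory=NoiseParams)
    scatter_preferences: bool = True
    tw_hrf: str = "gamma"
    bd_hrf: str = "double_gamma"


@dataclass
class SyntheticCohortDataset:
    config: CohortConfig
    subjects: List[SubjectSpec]
    truths: Dict[str, GroundTruthMap]
    tw_runs: Dict[str, List[Tuple[RunDescriptor, np.ndarray]]]
    bd_runs: Dict[str, List[Tuple[RunDescriptor, np.ndarray]]]
    seed: int = 0

    def subjects_in(self, group: str) -> List[SubjectSpec]:
        return [s for s in self.subjects if s.group == group]

    def subject(self, subject_id: str) -> SubjectSpec:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)


def make_truth(
    grid_shape: Tuple[int, int, int] = (20, 20, 10),
    amplitude: float = 1.0,
    tuning_width: float = 1.0,
) -> GroundTruthMap:
    """Template ground truth: hand slab with a thumb->little gradient, CSF block.

    The hand slab spans the full first axis (the somatotopic gradient axis) in
    the middle of the lattice; a disjoint CSF block sits at the far edge with
    zero response amplitude everywhere.
    """
    nx, ny, nz = grid_shape
    if nx < 5 or ny < 4 or nz < 2:
        raise ValueError("grid too small; need at least 5 x 4 x 2")
    pref = np.zeros(grid_shape, dtype=int)
    width = np.zeros(grid_shape)
    amp = np.zeros(grid_shape)
    roi = np.full(grid_shape, ROI_BACKGROUND, dtype=int)

    y0, y1 = ny // 4, max(ny // 4 + 2, ny // 2)
    z0, z1 = 0, max(1, nz // 2)
    hand = np.zeros(grid_shape, dtype=bool)
    hand[:, y0:y1, z0:z1] = True
    roi[hand] = ROI_HAND
    # monotone finger gradient along axis 0
    finger_of_x = 1 + (np.arange(nx) * 5) // nx
    pref[hand] = np.broadcast_to(finger_of_x[:, None, None], grid_shape)[hand]
    width[hand] = tuning_width
    amp[hand] = amplitude

    csf = np.zeros(grid_shape, dtype=bool)
    csf[:, ny - max(2, ny // 5) :, nz - max(1, nz // 4) :] = True
    csf &= ~hand
    roi[csf] = ROI_CSF

    return GroundTruthMap(
        grid_shape=grid_shape,
        preferred_finger=pref.ravel(),
        tuning_width=width.ravel(),
        amplitude=amp.ravel(),
        roi_labels=roi.ravel(),
    )


def subject_truth(
    base: GroundTruthMap, subject: SubjectSpec, rng: np.random.Generator, scatter: bool = True
) -> GroundTruthMap:
    """Per-subject truth: preferred fingers scattered with probability delta."""
    pref = base.preferred_finger.copy()
    if scatter and subject.deterioration > 0:
        tuned = np.flatnonzero(base.tuned_mask)
        hit = tuned[rng.random(tuned.size) < subject.deterioration]
        pref[hit] = rng.integers(1, 6, size=hit.size)
    return GroundTruthMap(
        grid_shape=base.grid_shape,
        preferred_finger=pref,
        tuning_width=base.tuning_width.copy(),
        amplitude=base.amplitude.copy(),
        roi_labels=base.roi_labels.copy(),
    )


def response_profiles(truth: GroundTruthMap, delta: float) -> np.ndarray:
    """Noiseless (n_voxels, 5) response amplitude per finger condition.

    Tuned profile: ``amplitude * exp(-(finger - preferred)^2 / (2 w^2))``.
    Deterioration mixes toward the voxel's finger-mean profile, preserving the
    mean response over fingers exactly.
    """
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must lie in [0, 1]")
    fingers = np.arange(1, 6)
    dist = fingers[None, :] - truth.preferred_finger[:, None].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(truth.tuning_width > 0, truth.tuning_width, 1.0)
        tuned = truth.amplitude[:, None] * np.exp(-(dist**2) / (2.0 * w[:, None] ** 2))
    tuned[~truth.tuned_mask] = 0.0
    uniform = np.repeat(tuned.mean(axis=1, keepdims=True), 5, axis=1)
    return (1.0 - delta) * tuned + delta * uniform


def _add_noise(
    signal: np.ndarray, noise: NoiseParams, rng: np.random.Generator
) -> np.ndarray:
    if noise.sigma == 0:
        return signal
    eps = rng.normal(0.0, noise.sigma, size=signal.shape)
    if noise.ar_rho:
        rho = noise.ar_rho
        if not -1 < rho < 1:
            raise ValueError("AR(1) rho must lie in (-1, 1)")
        # innovation scaling keeps the marginal variance at sigma^2
        eps = lfilter([np.sqrt(1 - rho**2)], [1.0, -rho], eps, axis=-1)
        eps[..., 0] = rng.normal(0.0, noise.sigma, size=eps.shape[:-1])
    return signal + eps


def simulate_run(
    subject: SubjectSpec,
    truth: GroundTruthMap,
    run: RunDescriptor,
    noise: NoiseParams,
    seed: int,
    config: Optional[CohortConfig] = None,
) -> np.ndarray:
    """One run's (n_voxels, n_volumes) matrix in % signal units around zero."""
    cfg = config or CohortConfig(grid_shape=truth.grid_shape)
    if tuple(truth.grid_shape) != tuple(cfg.grid_shape):
        raise ValueError(
            f"truth grid {truth.grid_shape} does not match config grid {cfg.grid_shape}"
        )
    hrf_kind = cfg.tw_hrf if run.kind == "travelwave" else cfg.bd_hrf
    regs = condition_regressors(cfg.design, run, hrf_kind)  # (T, 5)
    resp = response_profiles(truth, subject.deterioration)  # (V, 5)
    signal = resp @ regs.T
    rng = np.random.default_rng(seed)
    return _add_noise(signal, noise, rng)


def _sci_covariates(years: float, rng: np.random.Generator) -> dict:
    delta = min(years / DETERIORATION_YEARS_SCALE, 1.0)
    return dict(
        years_since_sci=years,
        motor_score=float(np.clip(50.0 * (1.0 - delta) + rng.normal(0, 4.0), 0, 50)),
        sensory_score=float(np.clip(24.0 * (1.0 - delta) + rng.normal(0, 3.0), 0, 24)),
        tissue_bridges=float(np.clip(3.0 * (1.0 - delta) + rng.normal(0, 0.5), 0, None)),
        cord_area=float(70.0 - 15.0 * delta + rng.normal(0, 3.0)),
    )


def generate_cohort(
    n_controls: int = 18,
    n_sci: int = 14,
    n_onehanders: int = 13,
    config: Optional[CohortConfig] = None,
    seed: int = 0,
) -> SyntheticCohortDataset:
    """Full synthetic cohort: every subject gets 4 travelling-wave + 4 blocked runs.

    A single cohort seed fans out to per-subject seed sequences, so the whole
    dataset is a pure function of ``(config, seed)``.
    """
    if min(n_controls, n_sci, n_onehanders) < 0:
        raise ValueError("cohort counts must be non-negative")
    cfg = config or CohortConfig()
    base = make_truth(cfg.grid_shape, cfg.amplitude, cfg.tuning_width)
    root = np.random.SeedSequence(seed)
    n_total = n_controls + n_sci + n_onehanders
    children = root.spawn(n_total)

    subjects: List[SubjectSpec] = []
    truths: Dict[str, GroundTruthMap] = {}
    tw_runs: Dict[str, List[Tuple[RunDescriptor, np.ndarray]]] = {}
    bd_runs: Dict[str, List[Tuple[RunDescriptor, np.ndarray]]] = {}

    roster = (
        [("control", i) for i in range(n_controls)]
        + [("sci", i) for i in range(n_sci)]
        + [("one_hander", i) for i in range(n_onehanders)]
    )
    for (group, g_idx), child in zip(roster, children):
        sub_rng = np.random.default_rng(child)
        sub_seed = int(child.generate_state(1)[0])
        if group == "control":
            sid = f"C{g_idx + 1:02d}"
            spec = SubjectSpec(sid, group, 0.0, sub_seed)
        elif group == "sci":
            sid = f"S{g_idx + 1:02d}"
            years = float(sub_rng.uniform(0.5, 33.0))
            delta = min(years / DETERIORATION_YEARS_SCALE, 1.0)
            spec = SubjectSpec(sid, group, delta, sub_seed, **_sci_covariates(years, sub_rng))
        else:
            sid = f"O{g_idx + 1:02d}"
            spec = SubjectSpec(sid, group, 1.0, sub_seed)
        subjects.append(spec)
        truths[sid] = subject_truth(base, spec, sub_rng, scatter=cfg.scatter_preferences)

        run_seeds = child.spawn(8)
        tw_list = []
        for run, rs in zip(default_travelwave_runs(cfg.design), run_seeds[:4]):
            mat = simulate_run(
                spec, truths[sid], run, cfg.noise, int(rs.generate_state(1)[0]), cfg
            )
            tw_list.append((run, mat))
        tw_runs[sid] = tw_list

        orders = make_blocked_orders(cfg.design, sub_rng)
        bd_list = []
        for i, (order, rs) in enumerate(zip(orders, run_seeds[4:])):
            run = RunDescriptor("blocked", i, order=order)
            mat = simulate_run(
                spec, truths[sid], run, cfg.noise, int(rs.generate_state(1)[0]), cfg
            )
            bd_list.append((run, mat))
        bd_runs[sid] = bd_list

    return SyntheticCohortDataset(cfg, subjects, truths, tw_runs, bd_runs, seed)
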