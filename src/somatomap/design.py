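"""Experimental design descriptions and condition-regressor construction.

Two acquisition designs are modelled:

* a travelling-wave design: fingers cued in a fixed cyclic order, 10 s per
  finger, 50 s per cycle, 7 cycles per run, 182 volumes at TR 2 s;
* a blocked design: 8 s blocks, five finger conditions plus rest, each
  repeated 5 times per run in a counterbalanced order, 127 volumes.

Both run types carry an initial rest baseline that absorbs the difference
between the task duration and the printed volume count (14 s by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .hrf import make_hrf, make_hrf_derivative

FINGERS = (1, 2, 3, 4, 5)
FORWARD_SEQUENCE = (1, 2, 3, 4, 5)
BACKWARD_SEQUENCE = (5, 4, 3, 2, 1)
REST = "rest"
FINE_DT = 0.1


@dataclass(frozen=True)
class DesignSpec:
    """Acquisition parameters for both run types, validated on construction."""

    tr_seconds: float = 2.0
    tw_block_on: float = 10.0
    tw_block_off: float = 40.0
    tw_cycles_per_run: int = 7
    tw_volumes_per_run: int = 182
    bd_block_seconds: float = 8.0
    bd_repeats_per_condition: int = 5
    bd_volumes_per_run: int = 127
    bd_runs: int = 4
    baseline_pad_seconds: float = 14.0

    def __post_init__(self) -> None:
        if self.tw_cycle_seconds != 5 * self.tw_block_on:
            raise ValueError("cycle length must equal 5 x single-finger block")
        tw_expected = self.tw_cycles_per_run * self.tw_cycle_seconds + self.baseline_pad_seconds
        if not np.isclose(self.tw_volumes_per_run * self.tr_seconds, tw_expected):
            raise ValueError(
                f"travelling-wave run: {self.tw_volumes_per_run} volumes x "
                f"{self.tr_seconds} s != {tw_expected} s"
            )
        bd_expected = (
            6 * self.bd_repeats_per_condition * self.bd_block_seconds + self.baseline_pad_seconds
        )
        if not np.isclose(self.bd_volumes_per_run * self.tr_seconds, bd_expected):
            raise ValueError(
                f"blocked run: {self.bd_volumes_per_run} volumes x "
                f"{self.tr_seconds} s != {bd_expected} s"
            )
        if self.tw_cycle_seconds % self.tr_seconds:
            raise ValueError("cycle length must be divisible by TR")

    @property
    def tw_cycle_seconds(self) -> float:
        return self.tw_block_on + self.tw_block_off

    @property
    def n_lags(self) -> int:
        return int(round(self.tw_cycle_seconds / self.tr_seconds))

    @property
    def pad_volumes(self) -> int:
        return int(round(self.baseline_pad_seconds / self.tr_seconds))

    @property
    def tw_cycle_volumes(self) -> int:
        return self.tw_cycles_per_run * self.n_lags

    @property
    def bd_conditions(self) -> tuple:
        return tuple(f"finger{i}" for i in FINGERS) + (REST,)

    @property
    def bd_n_blocks(self) -> int:
        return 6 * self.bd_repeats_per_condition


@dataclass(frozen=True)
class RunDescriptor:
    """One run of either design.

    ``sequence`` holds the cyclic finger order for travelling-wave runs;
    ``order`` holds the 30-block condition order for blocked runs.
    """

    kind: str  # "travelwave" | "blocked"
    index: int = 0
    sequence: tuple = ()
    order: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in ("travelwave", "blocked"):
            raise ValueError(f"unknown run kind {self.kind!r}")
        if self.kind == "travelwave" and tuple(sorted(self.sequence)) != FINGERS:
            raise ValueError("travelling-wave sequence must be a permutation of fingers 1..5")

    @property
    def direction(self) -> str:
        if self.kind != "travelwave":
            raise ValueError("direction is defined for travelling-wave runs only")
        return "forward" if tuple(self.sequence) == FORWARD_SEQUENCE else "backward"


def validate_blocked_order(design: DesignSpec, order: Sequence[str]) -> None:
    order = tuple(order)
    if len(order) != design.bd_n_blocks:
        raise ValueError(f"blocked order must contain {design.bd_n_blocks} blocks")
    for cond in design.bd_conditions:
        n = sum(o == cond for o in order)
        if n != design.bd_repeats_per_condition:
            raise ValueError(
                f"condition {cond!r} occurs {n} times, expected "
                f"{design.bd_repeats_per_condition}"
            )
    extra = set(order) - set(design.bd_conditions)
    if extra:
        raise ValueError(f"unknown conditions in order: {sorted(extra)}")


def make_blocked_orders(design: DesignSpec, rng: np.random.Generator) -> list:
    """Counterbalanced condition orders, one distinct order per run."""
    base = [c for c in design.bd_conditions for _ in range(design.bd_repeats_per_condition)]
    orders: list = []
    while len(orders) < design.bd_runs:
        cand = tuple(rng.permutation(base))
        if cand not in orders:
            orders.append(cand)
    return orders


def default_travelwave_runs(design: DesignSpec) -> list:
    """Two forward + two backward runs, interleaved F, B, F, B."""
    return [
        RunDescriptor("travelwave", 0, sequence=FORWARD_SEQUENCE),
        RunDescriptor("travelwave", 1, sequence=BACKWARD_SEQUENCE),
        RunDescriptor("travelwave", 2, sequence=FORWARD_SEQUENCE),
        RunDescriptor("travelwave", 3, sequence=BACKWARD_SEQUENCE),
    ]


def _finger_boxcars(design: DesignSpec, run: RunDescriptor, dt: float) -> np.ndarray:
    """Fine-grid (n_samples, 5) boxcar indicator of each finger's movement blocks."""
    if run.kind == "travelwave":
        n_vol = design.tw_volumes_per_run
        duration = n_vol * design.tr_seconds
        n = int(round(duration / dt))
        box = np.zeros((n, 5))
        for cycle in range(design.tw_cycles_per_run):
            start = design.baseline_pad_seconds + cycle * design.tw_cycle_seconds
            for pos, finger in enumerate(run.sequence):
                a = int(round((start + pos * design.tw_block_on) / dt))
                b = int(round((start + (pos + 1) * design.tw_block_on) / dt))
                box[a:b, finger - 1] = 1.0
        return box
    validate_blocked_order(design, run.order)
    n_vol = design.bd_volumes_per_run
    duration = n_vol * design.tr_seconds
    n = int(round(duration / dt))
    box = np.zeros((n, 5))
    for b_idx, cond in enumerate(run.order):
        if cond == REST:
            continue
        finger = int(cond.replace("finger", ""))
        start = design.baseline_pad_seconds + b_idx * design.bd_block_seconds
        a = int(round(start / dt))
        b = int(round((start + design.bd_block_seconds) / dt))
        box[a:b, finger - 1] = 1.0
    return box


def condition_regressors(
    design: DesignSpec,
    run: RunDescriptor,
    hrf_kind: str,
    dt: float = FINE_DT,
    derivative: bool = False,
) -> np.ndarray:
    """HRF-convolved finger regressors sampled at the TR.

    Returns an (n_volumes, 5) array; with ``derivative=True`` the boxcars are
    convolved with the HRF temporal derivative instead.
    """
    box = _finger_boxcars(design, run, dt)
    kern = (make_hrf_derivative if derivative else make_hrf)(hrf_kind, dt)
    n = box.shape[0]
    cols = [np.convolve(box[:, j], kern)[:n] * dt for j in range(5)]
    fine = np.column_stack(cols)
    step = int(round(design.tr_seconds / dt))
    n_vol = design.tw_volumes_per_run if run.kind == "travelwave" else design.bd_volumes_per_run
    sampled = fine[: n_vol * step : step]
    # Rescale so that a sustained block reaches ~unit height: normalise by the
    # peak of the convolved single-block response so amplitudes read in % units.
    ref_box = np.zeros(n)
    a = int(round(design.baseline_pad_seconds / dt))
    blk = design.tw_block_on if run.kind == "travelwave" else design.bd_block_seconds
    ref_box[a : a + int(round(blk / dt))] = 1.0
    peak = (np.convolve(ref_box, make_hrf(hrf_kind, dt))[:n] * dt).max()
    return sampled / peak
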