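"""Split-half Dice overlap analysis of finger maps.

The four travelling-wave runs are split into two halves (first forward +
first backward vs second forward + second backward), each half processed
into winner-take-all finger maps, thresholded (Z > 2 by default), and the
Dice overlap coefficient 2|A n B| / (|A| + |B|) computed for all 25
cross-half finger pairs, classified by neighbourhood distance |i - j|.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .travelwave import (
    FingerSelectivityMap,
    LagCorrelationMap,
    combine_runs_to_fingers,
    fdr_threshold,
)

CATEGORIES = ("same", "neighbour", "non_neighbour")


@dataclass
class BinaryFingerMasks:
    """Per-finger boolean voxel sets for one data half."""

    masks: Dict[int, np.ndarray]
    half: str
    threshold_rule: str

    def __getitem__(self, finger: int) -> np.ndarray:
        return self.masks[finger]


@dataclass
class DiceTable:
    pairs: pd.DataFrame  # columns: finger_a, finger_b, doc, category
    category_means: Dict[str, float]


def split_halves(
    maps: Sequence[LagCorrelationMap],
) -> Tuple[FingerSelectivityMap, FingerSelectivityMap]:
    """Split 2 forward + 2 backward lag maps into two half finger maps.

    Half 1 = first forward + first backward run; half 2 = the second of each.
    Each half goes through the identical finger-combination path as the full
    pipeline.
    """
    fwd = [m for m in maps if m.direction == "forward"]
    bwd = [m for m in maps if m.direction == "backward"]
    if len(fwd) != 2 or len(bwd) != 2:
        raise ValueError("need exactly 2 forward and 2 backward runs")
    half1 = combine_runs_to_fingers([fwd[0], bwd[0]])
    half2 = combine_runs_to_fingers([fwd[1], bwd[1]])
    return half1, half2


def threshold_finger_masks(
    fmap: FingerSelectivityMap,
    s1_mask: np.ndarray,
    half: str = "half1",
    rule: str = "z",
    z_threshold: float = 2.0,
    q: float = 0.05,
    n_eff: float = 175.0,
) -> BinaryFingerMasks:
    """Binary per-finger masks from a winner-take-all map within an S1 ROI.

    ``rule='z'`` keeps winner voxels whose standardised statistic
    ``winner_z * sqrt(n_eff - 3)`` exceeds ``z_threshold`` (the minimal Z > 2
    threshold; raw Fisher z has nominal SD 1/sqrt(n_eff - 3)); ``rule='fdr'``
    uses Benjamini-Hochberg q instead.  Masks are disjoint across fingers
    within a half by construction.
    """
    if s1_mask.shape[0] != fmap.n_voxels:
        raise ValueError("S1 mask does not match map grid")
    if rule == "z":
        keep = fmap.winner_z * np.sqrt(n_eff - 3.0) > z_threshold
    elif rule == "fdr":
        keep = fdr_threshold(fmap, q=q, n_eff=n_eff, mask=s1_mask).significant
    else:
        raise ValueError(f"unknown threshold rule {rule!r}")
    keep = keep & s1_mask
    masks = {f: keep & (fmap.winner_finger == f) for f in range(1, 6)}
    return BinaryFingerMasks(masks=masks, half=half, threshold_rule=rule)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap coefficient 2|A n B| / (|A| + |B|).

    Returns nan when both masks are empty (undefined overlap).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share one grid")
    denom = a.sum() + b.sum()
    if denom == 0:
        return float("nan")
    return float(2.0 * (a & b).sum() / denom)


def pair_category(i: int, j: int) -> str:
    d = abs(i - j)
    if d == 0:
        return "same"
    if d == 1:
        return "neighbour"
    return "non_neighbour"


def category_doc(half1: BinaryFingerMasks, half2: BinaryFingerMasks) -> DiceTable:
    """All 25 cross-half finger-pair DOCs plus per-category means.

    Pairs where both masks are empty contribute nan and are excluded from the
    category means.
    """
    rows = []
    for i in range(1, 6):
        for j in range(1, 6):
            rows.append(
                dict(
                    finger_a=i,
                    finger_b=j,
                    doc=dice(half1[i], half2[j]),
                    category=pair_category(i, j),
                )
            )
    df = pd.DataFrame(rows)
    means = {
        cat: float(df.loc[df.category == cat, "doc"].mean(skipna=True))
        for cat in CATEGORIES
    }
    return DiceTable(pairs=df, category_means=means)
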