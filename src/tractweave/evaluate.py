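"""Robustness and reliability evaluation of tractogram maps.

Four complementary analyses: Dice overlap of binary maps, hold-out
cross-validation of group probability maps (robustness across random
subject splits), repeated-processing reliability (the stochastic
tracker's upper reproducibility limit), and test-retest comparison of
sessions acquired at different time points.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .io import GeometryError, ScalarMap, SpatialTransform, apply_transform


@dataclass
class DiceReport:
    a: int
    b: int
    inter: int
    dice: float
    degenerate: bool = False     # both masks empty: dice defined as 1


def dice(map_a: ScalarMap, map_b: ScalarMap) -> DiceReport:
    """Dice overlap 2*N(A&B) / (N(A) + N(B)) of two binary maps.

    Requires identical grids; both-empty input is degenerate and scores
    1 with a flag so batch phantom runs do not crash.
    """
    if map_a.shape != map_b.shape or not np.allclose(map_a.affine, map_b.affine):
        raise GeometryError("dice requires maps on the same grid")
    a = int(np.count_nonzero(map_a.grid))
    b = int(np.count_nonzero(map_b.grid))
    inter = int(np.count_nonzero((map_a.grid != 0) & (map_b.grid != 0)))
    if a + b == 0:
        return DiceReport(a=0, b=0, inter=0, dice=1.0, degenerate=True)
    return DiceReport(a=a, b=b, inter=inter, dice=2.0 * inter / (a + b))


def _tukey_summary(values: np.ndarray) -> dict:
    """Box-and-whisker summary with Tukey 1.5*IQR whiskers."""
    v = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return {
        "mean": float(v.mean()), "median": float(med),
        "q1": float(q1), "q3": float(q3),
        "whisker_low": float(inside.min()) if len(inside) else float(v.min()),
        "whisker_high": float(inside.max()) if len(inside) else float(v.max()),
        "outliers": v[(v < lo_fence) | (v > hi_fence)].tolist(),
    }


@dataclass
class HoldOutResult:
    ratio: float
    n_iterations: int
    confidence: float
    dice_values: np.ndarray
    small_group_size: int = 0
    summary: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dice_values = np.asarray(self.dice_values, dtype=float)
        if not self.summary:
            self.summary = _tukey_summary(self.dice_values)


def holdout_cv(subject_binary_maps: list[ScalarMap],
               ratio: float = 0.10,
               n_iterations: int = 300,
               confidence: float = 0.05,
               rng: np.random.Generator | None = None) -> HoldOutResult:
    """Hold-out cross-validation of group probability-map consistency.

    Each iteration draws a random split with floor(ratio * n) subjects
    in the small group (at least 1) and the remainder in the large
    group, builds both groups' probability maps, thresholds them at the
    minimal confidence level, and records the Dice overlap.  A low
    spread signals that a robust probability map can be built from a
    small subset, i.e. no gross outlier subjects.
    """
    n = len(subject_binary_maps)
    if n < 3:
        raise ValueError("hold-out validation needs at least 3 subjects")
    small = max(1, int(np.floor(ratio * n)))
    if small >= n:
        raise ValueError("hold-out ratio leaves the large group empty")
    rng = rng or np.random.default_rng(0)

    # stack once: all maps share the grid
    ref = subject_binary_maps[0]
    for m in subject_binary_maps[1:]:
        if m.shape != ref.shape or not np.allclose(m.affine, ref.affine):
            raise GeometryError("subject maps must share one template grid")
    stack = np.stack([m.grid.astype(np.float64) for m in subject_binary_maps])

    values = np.empty(n_iterations)
    for it in range(n_iterations):
        perm = rng.permutation(n)
        small_ix, large_ix = perm[:small], perm[small:]
        pa = stack[small_ix].mean(axis=0) >= confidence - 1e-12
        pb = stack[large_ix].mean(axis=0) >= confidence - 1e-12
        sa, sb = int(pa.sum()), int(pb.sum())
        inter = int((pa & pb).sum())
        values[it] = 1.0 if sa + sb == 0 else 2.0 * inter / (sa + sb)
    return HoldOutResult(ratio=ratio, n_iterations=n_iterations,
                         confidence=confidence, dice_values=values,
                         small_group_size=small)


@dataclass
class ReliabilityResult:
    mode: str                       # 'repeated_processing' or 'test_retest'
    dice_values: np.ndarray
    pairs: list[tuple[int, int]]
    filtering: object | None = None
    summary: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dice_values = np.asarray(self.dice_values, dtype=float)
        if not self.summary and len(self.dice_values):
            self.summary = _tukey_summary(self.dice_values)


def repeated_processing(maps_per_run: list[ScalarMap],
                        filtering=None) -> ReliabilityResult:
    """Pairwise Dice over repeated identically-configured runs.

    R runs yield C(R, 2) = R*(R-1)/2 unordered pairs (45 for R = 10).
    """
    if len(maps_per_run) < 2:
        raise ValueError("repeated processing needs at least 2 runs")
    pairs = list(itertools.combinations(range(len(maps_per_run)), 2))
    values = [dice(maps_per_run[i], maps_per_run[j]).dice for i, j in pairs]
    return ReliabilityResult(mode="repeated_processing",
                             dice_values=np.asarray(values), pairs=pairs,
                             filtering=filtering)


def test_retest(map_t1: ScalarMap, map_t2: ScalarMap,
                transform_t2_to_t1: SpatialTransform | None = None) -> DiceReport:
    """Dice between two sessions after mapping session 2 onto session 1.

    The coregistration transform is consumed, not estimated; identity is
    allowed for phantoms.
    """
    t = transform_t2_to_t1 or SpatialTransform.identity()
    warped = apply_transform(map_t2, t, template=map_t1)
    return dice(map_t1, warped)


def roi_test_retest(pairs_by_cell: dict[tuple[str, str, str],
                                        list[tuple[ScalarMap, ScalarMap]]]
                    ) -> pd.DataFrame:
    """Session-pair ROI overlap table: mean +/- sd Dice per cell.

    ``pairs_by_cell`` maps (tract, roi_kind, hemisphere) — e.g.
    ('CST', 'seed', 'left') — to a list of (session1, session2) mask
    pairs.  Returns a tidy DataFrame with one row per cell; empty cells
    are omitted with a warning.
    """
    import warnings

    rows = []
    for (tract, kind, hemi), pairs in pairs_by_cell.items():
        if not pairs:
            warnings.warn(f"empty cell ({tract}, {kind}, {hemi}) omitted",
                          stacklevel=2)
            continue
        vals = np.array([dice(a, b).dice for a, b in pairs])
        rows.append({
            "tract": tract, "roi": kind, "hemisphere": hemi,
            "n_pairs": len(vals),
            "mean_dice": float(vals.mean()),
            "sd_dice": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        })
    return pd.DataFrame(rows, columns=["tract", "roi", "hemisphere",
                                       "n_pairs", "mean_dice", "sd_dice"])
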