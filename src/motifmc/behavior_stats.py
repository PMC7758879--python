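"""Behavioral assay statistics: food leaving, off-/on-food exploration.

Food-leaving probability is the per-minute fraction of worms leaving the
bacterial lawn (leavers in minute m divided by worms present at the start of
minute m), averaged over the observation window (default 15 min).  Minutes
that start with zero worms are excluded from the average: the per-minute
ratio is undefined there, and exclusion keeps assays with early full
departure well-defined.

Exploration plates are discretized into 0.25 cm^2 squares (0.5 cm side)
anchored at the food patch.  Off-food exploration assigns each square a ring
score by concentric Chebyshev shells around the patch: score 1 inside the
3x3 core, score k for the shell of the (2k+1)x(2k+1) square, capped at the
outermost declared ring (default 5).  On-food exploration is the percentage
of plate squares crossed by worm trails.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

DEFAULT_RING_SPEC: list[tuple[int, int]] = [
    (1, 9), (2, 25), (3, 49), (4, 81), (5, 121)]


@dataclass
class LeavingEventLog:
    """Per-minute worm counts for one food-leaving assay.

    ``minutes`` is an ordered list of (worms_at_start, leavers) pairs.
    Leaving is treated as absorbing within the window; an optional
    ``returns`` list restores worms at the start of the following minute.
    """

    minutes: list[tuple[int, int]]
    timepoint_h: float = 0.0
    returns: list[int] | None = None

    def __post_init__(self):
        rets = self.returns or [0] * len(self.minutes)
        if len(rets) != len(self.minutes):
            raise ValueError("returns must match minutes in length")
        for m, (start, leavers) in enumerate(self.minutes):
            if start < 0 or leavers < 0:
                raise ValueError(f"minute {m}: negative count")
            if leavers > start:
                raise ValueError(
                    f"minute {m}: {leavers} leavers exceed {start} worms "
                    f"at start")
            if m + 1 < len(self.minutes):
                expected = start - leavers + rets[m]
                nxt = self.minutes[m + 1][0]
                if nxt != expected:
                    raise ValueError(
                        f"minute {m + 1}: worms_at_start {nxt} != "
                        f"{expected} (previous start - leavers + returns)")

    @property
    def duration(self) -> int:
        return len(self.minutes)


@dataclass
class ExplorationGrid:
    """Boolean occupancy over the plate grid with the food patch location.

    ``occupancy[r, c]`` marks a 0.25 cm^2 square as showing bacterial growth
    (off-food assay) or worm trails (on-food assay).  ``patch_center`` is the
    (row, col) of the square containing the food patch.
    """

    occupancy: np.ndarray
    patch_center: tuple[int, int]
    square_side_cm: float = 0.5
    ring_spec: list[tuple[int, int]] = field(
        default_factory=lambda: list(DEFAULT_RING_SPEC))

    def __post_init__(self):
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.ndim != 2:
            raise ValueError("occupancy must be a 2-D matrix")
        r, c = self.patch_center
        nr, nc = self.occupancy.shape
        if not (0 <= r < nr and 0 <= c < nc):
            raise ValueError(f"patch_center {self.patch_center} outside "
                             f"{self.occupancy.shape} grid")
        scores = [s for s, _ in self.ring_spec]
        if scores != sorted(scores) or len(set(scores)) != len(scores):
            raise ValueError("ring scores must be strictly increasing")


@dataclass
class ExplorationScore:
    """Per-square ring scores and their aggregate."""

    per_square_scores: dict[tuple[int, int], int]
    total: float
    aggregation: str


def leaving_probability(log: LeavingEventLog) -> float:
    """Mean over minutes of (leavers / worms at start of that minute).

    Minutes starting with zero worms are excluded from the average.
    Appending such minutes therefore never changes the statistic.
    """
    ratios = [leavers / start for start, leavers in log.minutes if start > 0]
    if not ratios:
        raise ValueError("no minutes with worms present")
    return float(np.mean(ratios))


def ring_of_square(square: tuple[int, int], patch_center: tuple[int, int],
                   ring_spec: list[tuple[int, int]] | None = None) -> int:
    """Ring score of a grid square around the patch center.

    Score k is the Chebyshev shell index: the smallest centered odd square
    (2k+1)x(2k+1) containing the square (3x3 -> 1, 5x5 -> 2, ...).  The
    patch's own 3x3 core scores 1; squares beyond the outermost declared
    ring take the maximum declared score.
    """
    if ring_spec is None:
        ring_spec = DEFAULT_RING_SPEC
    d = max(abs(square[0] - patch_center[0]),
            abs(square[1] - patch_center[1]))
    ring = max(d, 1)
    max_score = ring_spec[-1][0]
    return min(ring, max_score)


def ring_membership_counts(geometry: str = "shell",
                           ring_spec: list[tuple[int, int]] | None = None
                           ) -> dict[int, int]:
    """Number of squares belonging to each ring, by geometry mode.

    ``"shell"``: concentric Chebyshev annuli around the 3x3 core — sizes
    9, 16, 24, 32, 40 for rings 1..5.  ``"literal"``: nested-square
    cumulative membership, where ring k's region is the full
    (2k+1)x(2k+1) square — the declared sizes 9, 25, 49, 81, 121.  The
    square-to-score assignment (smallest containing square) is identical in
    both modes; only the reported membership counts differ.
    """
    if ring_spec is None:
        ring_spec = DEFAULT_RING_SPEC
    if geometry == "shell":
        out = {}
        for k, _ in ring_spec:
            side = 2 * k + 1
            inner = 2 * k - 1
            out[k] = side * side - (inner * inner if k > 1 else 0)
        return out
    if geometry == "literal":
        return {k: declared for k, declared in ring_spec}
    raise ValueError(f"geometry must be 'shell' or 'literal', "
                     f"got {geometry!r}")


def off_food_score(grid: ExplorationGrid, aggregation: str = "sum"
                   ) -> ExplorationScore:
    """Score bacterial growth outside the food patch across the ring grid.

    Each occupied square outside the patch gets its ring score; the total is
    the chosen aggregation (sum, max or mean) over occupied squares.
    """
    if aggregation not in ("sum", "max", "mean"):
        raise ValueError(f"aggregation must be sum/max/mean, "
                         f"got {aggregation!r}")
    per_square: dict[tuple[int, int], int] = {}
    for r, c in zip(*np.nonzero(grid.occupancy)):
        sq = (int(r), int(c))
        if sq == grid.patch_center:
            continue  # the patch square itself is not exploration
        per_square[sq] = ring_of_square(sq, grid.patch_center, grid.ring_spec)
    if not per_square:
        warnings.warn("no bacterial growth outside the patch; score 0",
                      stacklevel=2)
        return ExplorationScore({}, 0.0, aggregation)
    values = list(per_square.values())
    if aggregation == "sum":
        total = float(sum(values))
    elif aggregation == "max":
        total = float(max(values))
    else:
        total = float(np.mean(values))
    return ExplorationScore(per_square, total, aggregation)


def on_food_coverage(grid: ExplorationGrid) -> float:
    """Percent of plate squares crossed by trails: 100 * occupied / total."""
    total = grid.occupancy.size
    if total == 0:
        raise ValueError("plate grid has zero squares")
    return 100.0 * float(np.count_nonzero(grid.occupancy)) / total


def read_leaving_log(path: str | Path) -> list[LeavingEventLog]:
    """Read leaving logs from tab-separated text.

    Columns: assay_id, timepoint_h, minute, worms_at_start, leavers.
    Returns one log per (assay_id, timepoint_h), minutes ordered.
    """
    rows: dict[tuple[str, float], list[tuple[int, int, int]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["assay_id", "timepoint_h", "minute", "worms_at_start",
                    "leavers"]
        if header != expected:
            raise ValueError(f"{path}: expected header {expected}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            assay, tp, minute, start, leavers = line.split("\t")
            rows.setdefault((assay, float(tp)), []).append(
                (int(minute), int(start), int(leavers)))
    logs = []
    for (assay, tp), minutes in sorted(rows.items()):
        minutes.sort()
        logs.append(LeavingEventLog(
            minutes=[(s, l) for _, s, l in minutes], timepoint_h=tp))
    return logs


def read_grid(path: str | Path) -> ExplorationGrid:
    """Read a grid from tab-separated text.

    First line: `patch<TAB>row<TAB>col`; following lines: 0/1 matrix rows.
    """
    with open(path) as fh:
        first = fh.readline().rstrip("\n").split("\t")
        if len(first) != 3 or first[0] != "patch":
            raise ValueError(f"{path}: expected first line "
                             f"'patch<TAB>row<TAB>col'")
        center = (int(first[1]), int(first[2]))
        matrix = [[bool(int(v)) for v in line.rstrip("\n").split("\t")]
                  for line in fh if line.strip()]
    return ExplorationGrid(np.array(matrix, dtype=bool), center)


def write_grid(grid: ExplorationGrid, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"patch\t{grid.patch_center[0]}\t{grid.patch_center[1]}\n")
        for row in grid.occupancy.astype(int):
            fh.write("\t".join(str(v) for v in row) + "\n")
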