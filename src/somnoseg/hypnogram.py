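"""Label algebra for epoch-free sleep/wake scoring.

Two label worlds coexist in this package:

* conventional AASM scoring — 30-second epoch stages (W/N1/N2/N3/REM)
  plus arousal event intervals; and
* temporally continuous scoring — gap-free SLEEP / WAKE_LIKE intervals
  with no epoch boundaries or duration limits.

This module converts between them and implements the post hoc scoring
modifications that move conventional labels toward continuous ones:
binarization of stages, overlay of arousals at 1-second resolution, and
a heuristic correction of sleep-to-wake transition points. It also
implements the post-prediction smoothing of standalone 1-second
segments driven by the model's class probabilities.

All times are seconds, intervals half-open ``[onset, offset)``. Binary
labels use 0 = SLEEP, 1 = WAKE_LIKE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import ContractError, FormatError, ValidationError

logger = logging.getLogger(__name__)

SLEEP = 0
WAKE_LIKE = 1

STAGES = ("W", "N1", "N2", "N3", "REM")
SLEEP_STAGES = frozenset({"N1", "N2", "N3", "REM"})
ALLOWED_RESOLUTIONS = (1, 3, 5, 10, 15, 30)


@dataclass(frozen=True)
class EpochHypnogram:
    """Conventional fixed-epoch stage sequence."""

    stages: tuple[str, ...]
    epoch_len_s: float = 30.0
    onset_s: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "stages", tuple(self.stages))
        if self.epoch_len_s <= 0:
            raise ContractError("epoch_len_s must be > 0")
        if not self.stages:
            raise ContractError("EpochHypnogram requires at least one epoch")

    @property
    def duration_s(self) -> float:
        return len(self.stages) * self.epoch_len_s

    def epoch_onset(self, index: int) -> float:
        return self.onset_s + index * self.epoch_len_s


@dataclass(frozen=True)
class ArousalEvents:
    """Sorted, non-overlapping arousal intervals."""

    events: tuple[tuple[float, float], ...]
    validate_min_duration: bool = False

    def __post_init__(self) -> None:
        evs = tuple((float(a), float(b)) for a, b in self.events)
        object.__setattr__(self, "events", evs)
        prev_end = -np.inf
        for i, (a, b) in enumerate(evs):
            if b <= a:
                raise ContractError(f"arousal {i}: offset {b} <= onset {a}")
            if a < prev_end:
                raise ContractError(f"arousal {i} overlaps its predecessor")
            if self.validate_min_duration and b - a < 3.0 - 1e-9:
                raise ValidationError(
                    f"arousal {i} shorter than the 3 s minimum: [{a}, {b})"
                )
            prev_end = b

    def __len__(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class ContinuousHypnogram:
    """Gap-free alternating SLEEP/WAKE_LIKE intervals (canonical form)."""

    intervals: tuple[tuple[float, float, int], ...]

    def __post_init__(self) -> None:
        ivs = tuple((float(a), float(b), int(s)) for a, b, s in self.intervals)
        object.__setattr__(self, "intervals", ivs)
        if not ivs:
            raise ContractError("ContinuousHypnogram requires >= 1 interval")
        for i, (a, b, s) in enumerate(ivs):
            if b <= a:
                raise ContractError(f"interval {i}: offset {b} <= onset {a}")
            if s not in (SLEEP, WAKE_LIKE):
                raise ContractError(f"interval {i}: state {s} not in {{0, 1}}")
            if i > 0:
                if abs(a - ivs[i - 1][1]) > 1e-9:
                    raise ContractError(f"gap/overlap between intervals {i-1} and {i}")
                if s == ivs[i - 1][2]:
                    raise ContractError(
                        f"intervals {i-1} and {i} share state {s}; merge first"
                    )

    @classmethod
    def from_intervals(cls, intervals) -> "ContinuousHypnogram":
        """Build from possibly unmerged, contiguous intervals."""
        merged: list[list] = []
        for a, b, s in intervals:
            if merged and merged[-1][2] == int(s):
                merged[-1][1] = float(b)
            else:
                merged.append([float(a), float(b), int(s)])
        return cls(tuple((a, b, s) for a, b, s in merged))

    @property
    def onset_s(self) -> float:
        return self.intervals[0][0]

    @property
    def offset_s(self) -> float:
        return self.intervals[-1][1]

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    def state_duration(self, state: int) -> float:
        return sum(b - a for a, b, s in self.intervals if s == state)


@dataclass(frozen=True)
class GridLabels:
    """Binary labels on a regular grid of one of the supported resolutions."""

    labels: np.ndarray
    resolution_s: int
    onset_s: float = 0.0

    def __post_init__(self) -> None:
        if self.resolution_s not in ALLOWED_RESOLUTIONS:
            raise ContractError(
                f"resolution_s must be one of {ALLOWED_RESOLUTIONS}, "
                f"got {self.resolution_s}"
            )
        arr = np.asarray(self.labels, dtype=np.uint8)
        if arr.ndim != 1 or arr.size == 0:
            raise ContractError("labels must be a nonempty 1-D array")
        if not np.all((arr == SLEEP) | (arr == WAKE_LIKE)):
            raise ContractError("labels must be binary (0 = SLEEP, 1 = WAKE_LIKE)")
        object.__setattr__(self, "labels", arr)

    def __len__(self) -> int:
        return self.labels.size

    @property
    def duration_s(self) -> float:
        return self.labels.size * self.resolution_s


@dataclass(frozen=True)
class ProbabilityTrack:
    """Per-grid-cell probability of WAKE_LIKE (p_sleep = 1 - p_wake)."""

    p_wake: np.ndarray
    resolution_s: int
    onset_s: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.p_wake, dtype=np.float64)
        if arr.ndim != 1 or arr.size == 0:
            raise ContractError("p_wake must be a nonempty 1-D array")
        if np.any(arr < -1e-9) or np.any(arr > 1 + 1e-9):
            raise ContractError("p_wake values must lie in [0, 1]")
        object.__setattr__(self, "p_wake", np.clip(arr, 0.0, 1.0))

    def __len__(self) -> int:
        return self.p_wake.size

    def argmax_labels(self) -> GridLabels:
        """Hard labels; the p = 0.5 tie resolves to WAKE_LIKE."""
        return GridLabels((self.p_wake >= 0.5).astype(np.uint8),
                          self.resolution_s, self.onset_s)


# ---------------------------------------------------------------------------
# Core conversions
# ---------------------------------------------------------------------------

def stages_to_binary(epochs: EpochHypnogram) -> GridLabels:
    """Binarize stages: W -> WAKE_LIKE, {N1, N2, N3, REM} -> SLEEP."""
    if epochs.epoch_len_s != 30:
        raise ContractError("stages_to_binary expects 30-second epochs")
    out = np.empty(len(epochs.stages), dtype=np.uint8)
    for i, st in enumerate(epochs.stages):
        if st == "W":
            out[i] = WAKE_LIKE
        elif st in SLEEP_STAGES:
            out[i] = SLEEP
        else:
            raise ValidationError(f"unknown stage {st!r} at epoch index {i}")
    return GridLabels(out, 30, epochs.onset_s)


def expand_grid(labels: GridLabels, target_resolution_s: int) -> GridLabels:
    """Refine the lattice by replicating each cell (e.g. 30 s -> 1 s)."""
    src = labels.resolution_s
    if src % target_resolution_s != 0:
        raise ContractError(
            f"target resolution {target_resolution_s} must divide source {src}"
        )
    factor = src // target_resolution_s
    return GridLabels(np.repeat(labels.labels, factor), target_resolution_s,
                      labels.onset_s)


def incorporate_arousals(labels: GridLabels, arousals: ArousalEvents) -> GridLabels:
    """Overlay arousals onto a 1-second grid as WAKE_LIKE.

    Every 1-second cell with nonzero overlap with any arousal interval
    becomes WAKE_LIKE; no cell is ever changed toward SLEEP (cells that
    are already WAKE_LIKE — e.g. from a wake-scored epoch — stay as
    they are). Arousals extending past the grid span are clipped.
    """
    if labels.resolution_s != 1:
        raise ContractError("incorporate_arousals requires a 1-second grid")
    out = labels.labels.copy()
    n = out.size
    for a, b in arousals.events:
        lo = a - labels.onset_s
        hi = b - labels.onset_s
        if lo < -1e-9 or hi > n + 1e-9:
            logger.warning(
                "arousal [%s, %s) extends outside the grid span; clipped", a, b
            )
        i0 = max(int(np.floor(lo + 1e-9)), 0)
        i1 = min(int(np.ceil(hi - 1e-9)), n)
        if i1 > i0:
            out[i0:i1] = WAKE_LIKE
    return replace(labels, labels=out)


def heuristic_correction(labels: GridLabels, arousals: ArousalEvents,
                         epochs: EpochHypnogram) -> GridLabels:
    """Refine sleep-to-wake transition points after arousal incorporation.

    When conventional scoring marks a whole 30-second epoch as wake, the
    true transition often happened at an arousal onset inside that
    epoch. For each arousal satisfying all of

    1. its onset falls in an epoch manually scored as wakefulness,
    2. the onset lies in the first half of that wake epoch (strictly
       before the midpoint), and
    3. the preceding epoch was scored as sleep,

    the 1-second cells from the epoch onset up to (not including) the
    arousal onset are reassigned to SLEEP. The first qualifying arousal
    in each epoch wins; cells at or after an arousal onset are never
    altered.
    """
    if labels.resolution_s != 1:
        raise ContractError("heuristic_correction requires a 1-second grid")
    el = epochs.epoch_len_s
    shift = labels.onset_s - epochs.onset_s
    if abs(shift - round(shift / el) * el) > 1e-9:
        raise ContractError("grid is not aligned to the 30-second epoch lattice")
    out = labels.labels.copy()
    corrected_epochs: set[int] = set()
    for a_on, _a_off in arousals.events:
        e = int(np.floor((a_on - epochs.onset_s) / el + 1e-9))
        if e < 1 or e >= len(epochs.stages):
            continue
        if e in corrected_epochs:
            continue
        if epochs.stages[e] != "W":
            continue
        epoch_onset = epochs.epoch_onset(e)
        if not (a_on < epoch_onset + el / 2):  # strictly in the first half
            continue
        if epochs.stages[e - 1] == "W":
            continue
        i0 = int(round(epoch_onset - labels.onset_s))
        i1 = i0 + int(np.floor(a_on - epoch_onset + 1e-9))
        i0, i1 = max(i0, 0), min(i1, out.size)
        if i1 > i0:
            out[i0:i1] = SLEEP
        corrected_epochs.add(e)
    return replace(labels, labels=out)


def build_labels(epochs: EpochHypnogram, arousals: ArousalEvents | None,
                 mode: str = "modified") -> GridLabels:
    """Construct 1-second training labels from conventional scoring.

    ``mode='conventional'`` is plain binarized staging expanded to 1 s;
    ``mode='modified'`` additionally overlays arousals and applies the
    heuristic sleep-to-wake transition correction.
    """
    grid = expand_grid(stages_to_binary(epochs), 1)
    if mode == "conventional":
        return grid
    if mode != "modified":
        raise ContractError(f"mode must be 'conventional' or 'modified', got {mode!r}")
    arousals = arousals or ArousalEvents(())
    grid = incorporate_arousals(grid, arousals)
    return heuristic_correction(grid, arousals, epochs)


# ---------------------------------------------------------------------------
# Continuous <-> grid
# ---------------------------------------------------------------------------

def _cumulative_wake(cont: ContinuousHypnogram):
    """Knots and cumulative WAKE_LIKE occupancy for fast overlap queries."""
    knots = [cont.onset_s]
    cum = [0.0]
    for a, b, s in cont.intervals:
        knots.append(b)
        cum.append(cum[-1] + (b - a if s == WAKE_LIKE else 0.0))
    return np.asarray(knots), np.asarray(cum)


def wake_overlap(cont: ContinuousHypnogram, edges: np.ndarray) -> np.ndarray:
    """WAKE_LIKE occupancy (s) of each window between consecutive edges."""
    knots, cum = _cumulative_wake(cont)
    at = np.interp(edges, knots, cum)
    return np.diff(at)


def rasterize(cont: ContinuousHypnogram, resolution_s: int) -> GridLabels:
    """Discretize continuous intervals onto a regular grid by majority.

    Each cell takes the state occupying the strict majority of it; an
    exact 50/50 split resolves to WAKE_LIKE. Only cells fully inside
    the annotation span are produced.
    """
    if resolution_s not in ALLOWED_RESOLUTIONS:
        raise ContractError(f"resolution_s must be one of {ALLOWED_RESOLUTIONS}")
    n = int(np.floor(cont.duration_s / resolution_s + 1e-9))
    if n < 1:
        raise ContractError(
            f"annotation span {cont.duration_s} s shorter than one "
            f"{resolution_s} s cell"
        )
    edges = cont.onset_s + resolution_s * np.arange(n + 1, dtype=np.float64)
    wake = wake_overlap(cont, edges)
    labels = (wake >= resolution_s / 2 - 1e-9).astype(np.uint8)
    return GridLabels(labels, resolution_s, cont.onset_s)


def grid_to_intervals(labels: GridLabels) -> ContinuousHypnogram:
    """Run-length encode a grid into canonical merged intervals."""
    arr = labels.labels
    change = np.flatnonzero(np.diff(arr)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [arr.size]))
    res = labels.resolution_s
    return ContinuousHypnogram(tuple(
        (labels.onset_s + s * res, labels.onset_s + e * res, int(arr[s]))
        for s, e in zip(starts, ends)
    ))


# ---------------------------------------------------------------------------
# Standalone-segment smoothing
# ---------------------------------------------------------------------------

def smooth_standalone(labels: GridLabels, probs: ProbabilityTrack) -> GridLabels:
    """Smooth standalone 1-second predictions using class probabilities.

    A standalone cell is a single cell whose two immediate neighbours
    both carry the opposite class. Standalones are detected on the
    unmodified input and processed left to right on a working copy: the
    mean probability of the standalone's class over the 3-second window
    centred on it decides the edit — below 0.5 the lone cell is flipped
    to the surrounding class, otherwise the whole 3-second window is
    reassigned to the standalone's class. Cells outside these windows
    are never touched.
    """
    if labels.resolution_s != 1 or probs.resolution_s != 1:
        raise ContractError("smooth_standalone requires 1-second grids")
    if len(labels) != len(probs):
        raise ContractError("labels and probabilities must share the grid")
    if not np.array_equal(labels.labels, probs.argmax_labels().labels):
        logger.warning(
            "smooth_standalone: labels are not the argmax of the supplied "
            "probabilities; proceeding with the labels as given"
        )
    x = labels.labels
    p_wake = probs.p_wake
    out = x.copy()
    n = x.size
    for t in range(1, n - 1):
        if x[t - 1] == x[t + 1] != x[t]:
            cls = x[t]
            p_cls = p_wake[t - 1:t + 2] if cls == WAKE_LIKE \
                else 1.0 - p_wake[t - 1:t + 2]
            if float(np.mean(p_cls)) < 0.5:
                out[t] = x[t - 1]
            else:
                out[t - 1:t + 2] = cls
    return replace(labels, labels=out)


# ---------------------------------------------------------------------------
# Plain-text I/O
# ---------------------------------------------------------------------------

def write_epochs_tsv(epochs: EpochHypnogram, path) -> None:
    lines = [f"{i}\t{st}" for i, st in enumerate(epochs.stages)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_epochs_tsv(path, epoch_len_s: float = 30.0,
                    onset_s: float = 0.0) -> EpochHypnogram:
    stages = []
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}: expected 'epoch_index<TAB>stage' lines")
        stages.append(parts[1].strip())
    return EpochHypnogram(tuple(stages), epoch_len_s, onset_s)


def write_intervals_tsv(intervals, path) -> None:
    """Write (onset, offset[, state]) rows; accepts events or hypnograms."""
    if isinstance(intervals, ContinuousHypnogram):
        rows = [f"{a:.6f}\t{b:.6f}\t{s}" for a, b, s in intervals.intervals]
    elif isinstance(intervals, ArousalEvents):
        rows = [f"{a:.6f}\t{b:.6f}" for a, b in intervals.events]
    else:
        rows = ["\t".join(f"{v:.6f}" if isinstance(v, float) else str(v)
                          for v in row) for row in intervals]
    Path(path).write_text("\n".join(rows) + ("\n" if rows else ""))


def read_arousals_tsv(path) -> ArousalEvents:
    events = []
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        a, b = ln.split("\t")[:2]
        events.append((float(a), float(b)))
    return ArousalEvents(tuple(events))


def read_continuous_tsv(path) -> ContinuousHypnogram:
    intervals = []
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) != 3:
            raise FormatError(f"{path}: expected 'onset<TAB>offset<TAB>state' lines")
        state = parts[2].strip()
        s = {"0": SLEEP, "1": WAKE_LIKE, "SLEEP": SLEEP,
             "WAKE_LIKE": WAKE_LIKE}.get(state)
        if s is None:
            raise FormatError(f"{path}: unknown state {state!r}")
        intervals.append((float(parts[0]), float(parts[1]), s))
    return ContinuousHypnogram.from_intervals(intervals)


def write_grid_csv(labels: GridLabels, path) -> None:
    header = f"# resolution_s={labels.resolution_s} onset_s={labels.onset_s}\n"
    body = "\n".join(str(int(v)) for v in labels.labels)
    Path(path).write_text(header + body + "\n")


def read_grid_csv(path) -> GridLabels:
    lines = Path(path).read_text().splitlines()
    meta = dict(kv.split("=") for kv in lines[0].lstrip("# ").split())
    vals = np.array([int(ln) for ln in lines[1:] if ln.strip()], dtype=np.uint8)
    return GridLabels(vals, int(meta["resolution_s"]), float(meta["onset_s"]))


def write_probs_csv(probs: ProbabilityTrack, path) -> None:
    header = f"# resolution_s={probs.resolution_s} onset_s={probs.onset_s}\n"
    body = "\n".join(f"{v:.8f}" for v in probs.p_wake)
    Path(path).write_text(header + body + "\n")


def read_probs_csv(path) -> ProbabilityTrack:
    lines = Path(path).read_text().splitlines()
    meta = dict(kv.split("=") for kv in lines[0].lstrip("# ").split())
    vals = np.array([float(ln) for ln in lines[1:] if ln.strip()])
    return ProbabilityTrack(vals, int(meta["resolution_s"]), float(meta["onset_s"]))
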