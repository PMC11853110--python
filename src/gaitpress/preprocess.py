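"""Raw frame streams -> per-gait-cycle 32x32 average bilateral pressure maps.

Pipeline: anomaly replacement -> whole-traversal pressure accumulation ->
32x16 footprint ROI segmentation with spatial (cell coordinates) and
temporal (onset frame) bookkeeping -> stride-level gait-cycle detection
(N contacts yield N-1 cycles) -> per-cycle average maps, left and right
foot halves merged side by side into a 32x32 feature image -> optional
horizontal-flip augmentation and train/test partitioning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .simulate import PressureFrameSequence

__all__ = [
    "FootprintROI",
    "GaitCycle",
    "AveragePressureMap",
    "PartitionSpec",
    "replace_anomalies",
    "accumulate_pressure",
    "extract_rois",
    "detect_gait_cycles",
    "compute_average_map",
    "maps_from_sequence",
    "augment_flip",
    "build_datasets",
    "save_maps",
    "load_maps",
    "ROI_ROWS",
    "ROI_COLS",
]

ROI_ROWS = 32
ROI_COLS = 16


@dataclass(frozen=True)
class FootprintROI:
    """A single foot contact, localised by a 32x16 window on the mat."""

    row0: int
    col0: int
    side: str  # "left" | "right"
    onset_frame: int
    offset_frame: int
    coords_x: np.ndarray = field(repr=False)  # active-cell columns (mat frame)
    coords_y: np.ndarray = field(repr=False)  # active-cell rows (mat frame)
    mass: float = 0.0

    def __post_init__(self) -> None:
        if self.onset_frame > self.offset_frame:
            raise ValueError("onset_frame must not exceed offset_frame")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")

    @property
    def bounds(self) -> tuple[int, int]:
        return (self.row0, self.col0)


@dataclass(frozen=True)
class GaitCycle:
    """One stride: from a foot contact to the same foot's next contact."""

    index: int  # 1-based ordinal
    start_frame: int
    end_frame: int
    rois: tuple[FootprintROI, ...]

    def __post_init__(self) -> None:
        if self.end_frame - self.start_frame < 1:
            raise ValueError("cycle duration must be >= 1 frame")

    @property
    def duration_frames(self) -> int:
        return self.end_frame - self.start_frame


@dataclass
class AveragePressureMap:
    """32x32 bilateral per-cycle feature image (left half | right half)."""

    grid: np.ndarray
    subject_id: int
    condition: str
    cycle_index: int
    round_id: int = 0
    trial_id: int = 0
    augmented: bool = False

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.shape != (32, 32):
            raise ValueError("average map must be 32x32")
        if (self.grid < 0).any():
            raise ValueError("average map must be non-negative")


# ---------------------------------------------------------------------------
# anomaly replacement


def replace_anomalies(
    seq: PressureFrameSequence,
    z_threshold: float = 4.0,
    sd_floor: float = 4.0,
) -> PressureFrameSequence:
    """Replace isolated outlier cells by their 8-neighbourhood mean.

    A cell is flagged when it deviates from its 8-neighbourhood mean by
    more than ``z_threshold`` neighbourhood standard deviations (the SD is
    floored at ``sd_floor`` counts to keep flat regions from flagging
    quantisation jitter).  Flagged cells are replaced by the mean of their
    non-flagged neighbours; all other cells pass through unchanged.
    """
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    frames = seq.frames.astype(np.float64)
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    cleaned = frames.copy()
    for t in range(frames.shape[0]):
        f = frames[t]
        if not f.any():
            continue
        nsum = ndimage.convolve(f, kernel, mode="constant")
        nsqsum = ndimage.convolve(f * f, kernel, mode="constant")
        ncnt = ndimage.convolve(np.ones_like(f), kernel, mode="constant")
        nmean = nsum / ncnt
        nvar = np.maximum(nsqsum / ncnt - nmean**2, 0.0)
        nsd = np.maximum(np.sqrt(nvar), sd_floor)
        flagged = np.abs(f - nmean) > z_threshold * nsd
        if not flagged.any():
            continue
        for r, c in zip(*np.nonzero(flagged)):
            rs = slice(max(r - 1, 0), min(r + 2, f.shape[0]))
            cs = slice(max(c - 1, 0), min(c + 2, f.shape[1]))
            nb = f[rs, cs]
            ok = ~flagged[rs, cs]
            ok[min(r, 1), min(c, 1)] = False  # exclude the cell itself
            if ok.any():
                cleaned[t, r, c] = nb[ok].mean()
    out = np.clip(np.rint(cleaned), 0, 255).astype(seq.frames.dtype)
    return PressureFrameSequence(
        frames=out,
        subject_id=seq.subject_id,
        condition=seq.condition,
        trial_id=seq.trial_id,
        round_id=seq.round_id,
        sample_rate_hz=seq.sample_rate_hz,
    )


# ---------------------------------------------------------------------------
# accumulation and ROI extraction


def accumulate_pressure(seq: PressureFrameSequence) -> np.ndarray:
    """Cell-wise sum of all frames of one traversal (no 8-bit clipping)."""
    if seq.n_frames == 0:
        raise ValueError("cannot accumulate an empty sequence")
    return seq.frames.astype(np.int64).sum(axis=0)


def _center_window(center: float, size: int, limit: int) -> int:
    """Origin of a ``size``-cell window centred on ``center``, clipped.

    Uses the window's true cell-centre ``origin + (size - 1) / 2`` so that
    mirror-imaging the mat maps windows onto windows.
    """
    origin = int(round(center - (size - 1) / 2))
    return int(np.clip(origin, 0, limit - size))


def extract_rois(
    summed_map: np.ndarray,
    seq: PressureFrameSequence,
    min_mass: float = 50.0,
    localization: str = "component",
) -> list[FootprintROI]:
    """Segment individual footprints from the accumulated pressure map.

    Connected components of the active (nonzero) summed map are located
    (8-connectivity); each component of total mass >= ``min_mass`` becomes
    one ROI: a 32x16 window centred on the component's centre of mass,
    with the component's cell coordinates recorded and the onset/offset
    frames measured on the component's own cells.  ``localization`` may be
    ``"component"`` (default) or ``"correlation"``, which refines the
    window origin by maximising the windowed mass (a mask-correlation
    score) around the centre-of-mass position.

    Side is assigned from the component's lateral position relative to the
    mat mid-line.  ROIs are returned sorted by onset frame.
    """
    summed_map = np.asarray(summed_map)
    if summed_map.shape != seq.frames.shape[1:]:
        raise ValueError("summed map does not match sequence geometry")
    active = summed_map > 0
    labels, n_comp = ndimage.label(active, structure=np.ones((3, 3)))
    rois: list[FootprintROI] = []
    n_rows, n_cols = summed_map.shape
    for lab in range(1, n_comp + 1):
        mask = labels == lab
        mass = float(summed_map[mask].sum())
        if mass < min_mass:
            continue
        ys, xs = np.nonzero(mask)
        if np.ptp(ys) + 1 > ROI_ROWS or np.ptp(xs) + 1 > ROI_COLS:
            raise ValueError(
                f"footprint of extent {np.ptp(ys) + 1}x{np.ptp(xs) + 1} exceeds "
                f"the {ROI_ROWS}x{ROI_COLS} segmentation mask"
            )
        com_r, com_c = ndimage.center_of_mass(summed_map, labels, lab)
        r0 = _center_window(com_r, ROI_ROWS, n_rows)
        c0 = _center_window(com_c, ROI_COLS, n_cols)
        if localization == "correlation":
            r0, c0 = _refine_by_correlation(summed_map, mask, r0, c0)
        elif localization != "component":
            raise ValueError(f"unknown localization scheme {localization!r}")
        # temporal bookkeeping on the component's own cells
        cell_series = seq.frames[:, ys, xs]
        active_t = (cell_series > 0).any(axis=1)
        if not active_t.any():
            continue
        onset = int(np.argmax(active_t))
        offset = int(len(active_t) - 1 - np.argmax(active_t[::-1]))
        side = "left" if com_c < n_cols / 2 else "right"
        rois.append(
            FootprintROI(
                row0=r0,
                col0=c0,
                side=side,
                onset_frame=onset,
                offset_frame=offset,
                coords_x=xs,
                coords_y=ys,
                mass=mass,
            )
        )
    rois.sort(key=lambda r: (r.onset_frame, r.row0))
    return rois


def _refine_by_correlation(
    summed_map: np.ndarray, mask: np.ndarray, r0: int, c0: int, radius: int = 2
) -> tuple[int, int]:
    """Shift the window (within +/-radius) to maximise enclosed mass."""
    masked = np.where(mask, summed_map, 0)
    best = (-1.0, r0, c0)
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            r, c = r0 + dr, c0 + dc
            if r < 0 or c < 0 or r + ROI_ROWS > summed_map.shape[0] \
                    or c + ROI_COLS > summed_map.shape[1]:
                continue
            score = masked[r:r + ROI_ROWS, c:c + ROI_COLS].sum()
            if score > best[0]:
                best = (score, r, c)
    return best[1], best[2]


# ---------------------------------------------------------------------------
# gait cycles and average maps


def detect_gait_cycles(rois: Sequence[FootprintROI]) -> list[GaitCycle]:
    """Stride-level cycles from onset-sorted contacts: N contacts -> N-1.

    Cycle ``i`` runs from the onset of contact ``i`` to the onset of
    contact ``i + 2`` (same foot touching down again); the final cycle,
    lacking that landmark, is capped at the last contact's offset frame.
    """
    onsets = [r.onset_frame for r in rois]
    if onsets != sorted(onsets):
        raise ValueError("ROIs must be sorted by onset_frame")
    n = len(rois)
    cycles: list[GaitCycle] = []
    for i in range(n - 1):
        start = rois[i].onset_frame
        if i + 2 < n:
            end = rois[i + 2].onset_frame
        else:
            end = max(rois[-1].offset_frame + 1, start + 1)
        cycles.append(
            GaitCycle(
                index=i + 1,
                start_frame=start,
                end_frame=end,
                rois=(rois[i], rois[i + 1]),
            )
        )
    return cycles


def compute_average_map(
    seq: PressureFrameSequence, cycle: GaitCycle
) -> AveragePressureMap:
    """Average the two participating foot windows over one cycle.

    Each foot's 32x16 window is summed over the cycle's frames and divided
    by the cycle duration; the left-foot half occupies columns 0-15 of the
    32x32 output, the right-foot half columns 16-31.
    """
    if cycle.duration_frames < 1:
        raise ValueError("zero-duration cycle")
    if cycle.end_frame > seq.n_frames:
        raise ValueError("cycle extends beyond the sequence")
    grid = np.zeros((32, 32), dtype=np.float64)
    window = seq.frames[cycle.start_frame:cycle.end_frame].astype(np.float64)
    for roi in cycle.rois:
        sub = window[:, roi.row0:roi.row0 + ROI_ROWS,
                     roi.col0:roi.col0 + ROI_COLS].sum(axis=0)
        avg = sub / cycle.duration_frames
        half = slice(0, 16) if roi.side == "left" else slice(16, 32)
        grid[:, half] = avg
    return AveragePressureMap(
        grid=grid,
        subject_id=seq.subject_id,
        condition=seq.condition,
        cycle_index=cycle.index,
        round_id=seq.round_id,
        trial_id=seq.trial_id,
    )


def maps_from_sequence(
    seq: PressureFrameSequence,
    z_threshold: float | None = 4.0,
    min_mass: float = 50.0,
) -> list[AveragePressureMap]:
    """Full per-traversal preprocessing chain.

    ``z_threshold=None`` skips anomaly replacement (useful for noise-free
    synthetic input).
    """
    if z_threshold is not None:
        seq = replace_anomalies(seq, z_threshold)
    summed = accumulate_pressure(seq)
    rois = extract_rois(summed, seq, min_mass=min_mass)
    cycles = detect_gait_cycles(rois)
    return [compute_average_map(seq, cyc) for cyc in cycles]


# ---------------------------------------------------------------------------
# augmentation and dataset assembly


def augment_flip(maps: Iterable[AveragePressureMap]) -> list[AveragePressureMap]:
    """Originals plus horizontally mirrored copies (training data only)."""
    maps = list(maps)
    flipped = [
        replace_map(m, grid=np.fliplr(m.grid), augmented=True) for m in maps
    ]
    return maps + flipped


def replace_map(m: AveragePressureMap, **changes) -> AveragePressureMap:
    fields = dict(
        grid=m.grid, subject_id=m.subject_id, condition=m.condition,
        cycle_index=m.cycle_index, round_id=m.round_id, trial_id=m.trial_id,
        augmented=m.augmented,
    )
    fields.update(changes)
    return AveragePressureMap(**fields)


@dataclass(frozen=True)
class PartitionSpec:
    """Round/condition assignment of maps to train and test roles.

    ``train_rounds`` selects Type I rounds used for training.  For the
    open-set task ``known_subjects`` restricts training to enrolled
    identities; every map not in the training role lands in the test role.
    """

    train_rounds: tuple[int, ...] = (1, 2)
    train_condition: str = "type_i"
    known_subjects: tuple[int, ...] | None = None
    augment_training: bool = True

    @classmethod
    def closed_set(cls, augment: bool = True) -> "PartitionSpec":
        return cls(augment_training=augment)

    @classmethod
    def open_set(cls, known_subjects: Sequence[int],
                 augment: bool = True) -> "PartitionSpec":
        return cls(known_subjects=tuple(sorted(known_subjects)),
                   augment_training=augment)


def build_datasets(
    maps: Sequence[AveragePressureMap], spec: PartitionSpec
) -> dict[str, list[AveragePressureMap]]:
    """Partition cohort maps into disjoint train/test collections.

    Closed set: train on Type I rounds 1-2 of all subjects, test on the
    remaining rounds (Type I round 3 and the Type II round, kept separate
    by condition).  Open set: train only on the known subjects' training
    rounds; everything else — knowns' held-out rounds and all unknowns'
    maps — is test data.  Flip augmentation, when enabled, is applied to
    the training split only.
    """
    if any(m.augmented for m in maps):
        raise ValueError("build_datasets expects unaugmented maps")
    train: list[AveragePressureMap] = []
    test_i: list[AveragePressureMap] = []
    test_ii: list[AveragePressureMap] = []
    for m in maps:
        in_rounds = m.round_id in spec.train_rounds
        in_cond = m.condition == spec.train_condition
        known = (spec.known_subjects is None
                 or m.subject_id in spec.known_subjects)
        if in_rounds and in_cond and known:
            train.append(m)
        elif m.condition == "type_i":
            test_i.append(m)
        else:
            test_ii.append(m)
    train_keys = {(m.subject_id, m.round_id, m.trial_id, m.cycle_index)
                  for m in train}
    for m in test_i + test_ii:
        key = (m.subject_id, m.round_id, m.trial_id, m.cycle_index)
        if key in train_keys:
            raise ValueError(f"map {key} assigned to both train and test")
    out_train = augment_flip(train) if spec.augment_training else list(train)
    return {"train": out_train, "test_type_i": test_i,
            "test_type_ii": test_ii}


# ---------------------------------------------------------------------------
# persistence


def save_maps(maps: Sequence[AveragePressureMap], out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack = np.stack([m.grid for m in maps]) if maps else np.zeros((0, 32, 32))
    np.savez_compressed(out / "maps.npz", maps=stack.astype(np.float32))
    table = pd.DataFrame(
        [
            {
                "subject_id": m.subject_id,
                "condition": m.condition,
                "round_id": m.round_id,
                "trial_id": m.trial_id,
                "cycle_index": m.cycle_index,
                "augmented": m.augmented,
            }
            for m in maps
        ]
    )
    table.to_csv(out / "labels.csv", index=False)
    return out


def load_maps(in_dir: str | Path) -> list[AveragePressureMap]:
    in_dir = Path(in_dir)
    with np.load(in_dir / "maps.npz") as data:
        stack = data["maps"]
    table = pd.read_csv(in_dir / "labels.csv")
    return [
        AveragePressureMap(
            grid=stack[i],
            subject_id=int(rec["subject_id"]),
            condition=str(rec["condition"]),
            round_id=int(rec["round_id"]),
            trial_id=int(rec["trial_id"]),
            cycle_index=int(rec["cycle_index"]),
            augmented=bool(rec["augmented"]),
        )
        for i, rec in enumerate(table.to_dict("records"))
    ]
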