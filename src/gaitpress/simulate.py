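"""Synthetic pressure-mat walking data.

Emulates a piezoresistive walkway built from three 64 cm x 40 cm mat units
(1 cm sensor pitch, 192 x 40 = 7680 sensors, 40 Hz, 8-bit samples).  Each
simulated subject carries a bimodal (heel + forefoot) footprint template
whose extent follows one of four discrete shoe sizes, a weight-proportional
pressure magnitude, a per-foot outward step angle, and a stride length.
Walks alternate left/right contacts with a ~60 % stance / ~40 % swing phase
split, optionally perturbed by sensor noise and isolated anomaly spikes,
and optionally modified by a carried load that shifts the centre of
pressure and scales the magnitude.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "MatGeometry",
    "SubjectProfile",
    "WalkCondition",
    "PressureFrameSequence",
    "generate_cohort",
    "make_profile",
    "simulate_walk",
    "simulate_walk_float",
    "schedule_cohort_trials",
    "plan_round_walks",
    "save_trials",
    "load_trials",
    "COHORT_SHOE_SIZES",
    "PAPER_SHOE_SIZE_DISTRIBUTION",
]

#: The four discrete US shoe sizes worn by the study cohort.
COHORT_SHOE_SIZES = (3, 4, 7, 10)

#: Cohort shoe-size histogram: 2 subjects wore size 3, 15 size 4,
#: 19 size 7 and 24 size 10 (60 subjects total).
PAPER_SHOE_SIZE_DISTRIBUTION = {3: 2, 4: 15, 7: 19, 10: 24}

# Footprint extent (rows x cols of sensor cells) per shoe size.  Chosen so
# every rotated footprint fits the 32 x 16 segmentation mask and consecutive
# same-side contacts stay disjoint at the default stride.
_FOOT_EXTENT = {3: (20, 8), 4: (21, 8), 7: (23, 9), 10: (25, 10)}


@dataclass(frozen=True)
class MatGeometry:
    """Geometry and signal format of the sensing walkway."""

    n_units: int = 3
    unit_length_cm: int = 64
    unit_width_cm: int = 40
    sensor_pitch_cm: int = 1
    sample_rate_hz: int = 40
    value_max: int = 255

    @property
    def rows(self) -> int:
        """Cells along the walking direction."""
        return self.n_units * self.unit_length_cm // self.sensor_pitch_cm

    @property
    def cols(self) -> int:
        """Cells across the mat width."""
        return self.unit_width_cm // self.sensor_pitch_cm

    @property
    def n_sensors(self) -> int:
        return self.rows * self.cols


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject gait signature used by the walk generator.

    ``template_left``/``template_right`` are (heel, forefoot) lobe pairs,
    each a 32 x 16 non-negative intensity image on the segmentation-window
    grid; the full footprint at any instant is a stance-phase-dependent
    blend of the two lobes.
    """

    subject_id: int
    shoe_size_us: int
    weight_kg: float
    foot_len_cells: int
    foot_width_cells: int
    step_angle_deg: float
    stride_cells: int
    cadence_frames: int
    template_left: tuple[np.ndarray, np.ndarray] = field(repr=False)
    template_right: tuple[np.ndarray, np.ndarray] = field(repr=False)
    asymmetry: float = 1.0

    def __post_init__(self) -> None:
        if self.shoe_size_us not in COHORT_SHOE_SIZES:
            raise ValueError(
                f"shoe_size_us must be one of {COHORT_SHOE_SIZES}, "
                f"got {self.shoe_size_us}"
            )
        if self.weight_kg <= 0:
            raise ValueError("weight_kg must be positive")
        for heel, fore in (self.template_left, self.template_right):
            if heel.shape != (32, 16) or fore.shape != (32, 16):
                raise ValueError("templates must be 32x16")
            if (heel < 0).any() or (fore < 0).any():
                raise ValueError("templates must be non-negative")


@dataclass(frozen=True)
class WalkCondition:
    """Carried-load condition of a trial.

    ``load_g == 0`` is the unloaded Type I condition; the Type II condition
    carries a 500 g object, which shifts the centre of pressure forward by
    ``load_cop_shift_cells`` (rows, cols) and scales magnitude by
    ``load_scale``.
    """

    load_g: float = 0.0
    load_cop_shift_cells: tuple[int, int] = (0, 0)
    load_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.load_g == 0 and (
            self.load_cop_shift_cells != (0, 0) or self.load_scale != 1.0
        ):
            raise ValueError("load_g=0 requires zero COP shift and unit scale")

    @classmethod
    def type_i(cls) -> "WalkCondition":
        return cls()

    @classmethod
    def type_ii(cls, load_g: float = 500.0) -> "WalkCondition":
        # 500 g raises magnitude slightly and moves the COP one cell forward.
        return cls(load_g=load_g, load_cop_shift_cells=(1, 0), load_scale=1.05)

    @property
    def label(self) -> str:
        return "type_ii" if self.load_g > 0 else "type_i"


@dataclass
class PressureFrameSequence:
    """One traversal of the mat: a time-ordered stack of 8-bit frames."""

    frames: np.ndarray  # (T, rows, cols) uint8
    subject_id: int
    condition: str = "type_i"  # "type_i" | "type_ii"
    trial_id: int = 0
    round_id: int = 0
    sample_rate_hz: int = 40

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, rows, cols) stack")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


# ---------------------------------------------------------------------------
# cohort generation


def _make_lobes(
    rng: np.random.Generator,
    foot_len: int,
    foot_width: int,
    angle_deg: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Heel and forefoot pressure lobes rasterised onto the 32x16 window.

    Each lobe is an anisotropic Gaussian bump; the pair is rotated by the
    step angle about the footprint centre.  Peak intensity is 1; weight
    scaling is applied at walk time.
    """
    rows = np.arange(32, dtype=float)[:, None]
    cols = np.arange(16, dtype=float)[None, :]
    cr, cc = 15.5, 7.5  # window centre

    # Lobe centres before rotation: heel near the rear, forefoot near the
    # front of the foot box; small per-subject jitter individualises shape.
    heel_r = cr - foot_len / 2 + foot_len * (0.18 + 0.04 * rng.random())
    fore_r = cr - foot_len / 2 + foot_len * (0.72 + 0.06 * rng.random())
    heel_c = cc + rng.uniform(-0.8, 0.8)
    fore_c = cc + rng.uniform(-0.8, 0.8)

    theta = np.deg2rad(angle_deg)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    # foot-frame coordinates of every window cell
    dr = rows - cr
    dc = cols - cc
    r_f = cos_t * dr + sin_t * dc + cr
    c_f = -sin_t * dr + cos_t * dc + cc
    # hard crop to the rotated foot box so the footprint extent is exact
    in_box = (np.abs(r_f - cr) <= foot_len / 2) & (
        np.abs(c_f - cc) <= foot_width / 2
    )

    def lobe(center_r, center_c, sr, sc, amp):
        g = amp * np.exp(
            -(((r_f - center_r) / sr) ** 2 + ((c_f - center_c) / sc) ** 2)
        )
        return g * in_box

    heel = lobe(heel_r, heel_c, foot_len * 0.16, foot_width * 0.28,
                0.9 + 0.2 * rng.random())
    fore = lobe(fore_r, fore_c, foot_len * 0.20, foot_width * 0.34,
                0.9 + 0.2 * rng.random())
    # zero-out the numerical tails so the footprint has a crisp extent
    heel[heel < 0.05] = 0.0
    fore[fore < 0.05] = 0.0
    return heel, fore


def make_profile(
    subject_id: int,
    shoe_size_us: int,
    rng: np.random.Generator,
    *,
    weight_kg: float | None = None,
    identical_template_rng: np.random.Generator | None = None,
) -> SubjectProfile:
    """Draw a single subject profile.

    ``identical_template_rng`` forces the template/angle draws to come from
    a shared stream, producing deliberately indistinguishable subjects for
    chance-level control experiments.
    """
    if weight_kg is None:
        # cohort weights roughly 45-95 kg, loosely tied to shoe size
        base = {3: 50.0, 4: 57.0, 7: 68.0, 10: 78.0}[shoe_size_us]
        weight_kg = float(np.round(base + rng.normal(0, 8.0), 1))
        weight_kg = float(np.clip(weight_kg, 42.0, 98.0))
    foot_len, foot_width = _FOOT_EXTENT[shoe_size_us]
    t_rng = identical_template_rng if identical_template_rng is not None else rng
    angle = float(t_rng.uniform(2.0, 7.0))
    stride = int(t_rng.integers(14, 16))
    cadence = int(t_rng.integers(36, 45))
    tmpl_l = _make_lobes(t_rng, foot_len, foot_width, +angle)
    tmpl_r = _make_lobes(t_rng, foot_len, foot_width, -angle)
    return SubjectProfile(
        subject_id=subject_id,
        shoe_size_us=shoe_size_us,
        weight_kg=weight_kg,
        foot_len_cells=foot_len,
        foot_width_cells=foot_width,
        step_angle_deg=angle,
        stride_cells=stride,
        cadence_frames=cadence,
        template_left=tmpl_l,
        template_right=tmpl_r,
        asymmetry=float(t_rng.uniform(0.92, 1.08)),
    )


def generate_cohort(
    n_subjects: int,
    shoe_size_distribution: dict[int, int] | None = None,
    seed: int = 0,
    *,
    identical_templates: bool = False,
) -> list[SubjectProfile]:
    """Generate ``n_subjects`` profiles with a given shoe-size histogram.

    Parameters
    ----------
    shoe_size_distribution
        Mapping size -> count; must sum to ``n_subjects``.  Defaults to the
        60-subject cohort histogram scaled proportionally.
    identical_templates
        All subjects share one template/angle/stride draw (weights still
        vary); used as an indistinguishability control.
    """
    if shoe_size_distribution is None:
        shoe_size_distribution = _scaled_distribution(n_subjects)
    total = sum(shoe_size_distribution.values())
    if total != n_subjects:
        raise ValueError(
            f"shoe_size_distribution sums to {total}, expected {n_subjects}"
        )
    rng = np.random.default_rng(seed)
    sizes: list[int] = []
    for size in sorted(shoe_size_distribution):
        if size not in COHORT_SHOE_SIZES:
            raise ValueError(f"unsupported shoe size {size}")
        sizes.extend([size] * shoe_size_distribution[size])
    profiles = []
    for sid, size in enumerate(sizes):
        t_rng = np.random.default_rng(seed + 1) if identical_templates else None
        profiles.append(
            make_profile(sid, size, rng, identical_template_rng=t_rng)
        )
    if identical_templates and profiles:
        # exact clones of the first profile (identity is unlearnable)
        profiles = [
            dataclasses.replace(profiles[0], subject_id=p.subject_id)
            for p in profiles
        ]
    return profiles


def _scaled_distribution(n_subjects: int) -> dict[int, int]:
    """Scale the 60-subject histogram to ``n_subjects`` (largest remainder)."""
    if n_subjects == 0:
        return {}
    ref = PAPER_SHOE_SIZE_DISTRIBUTION
    total = sum(ref.values())
    raw = {s: n_subjects * c / total for s, c in ref.items()}
    out = {s: int(np.floor(v)) for s, v in raw.items()}
    rem = n_subjects - sum(out.values())
    for s in sorted(raw, key=lambda s: raw[s] - out[s], reverse=True)[:rem]:
        out[s] += 1
    return {s: c for s, c in out.items() if c > 0}


# ---------------------------------------------------------------------------
# walk simulation

_LEFT_LANE_COL = 3  # window-origin column of left-foot 32x16 windows
_RIGHT_LANE_COL = 21  # right-foot windows: columns 21..36


def simulate_walk_float(
    profile: SubjectProfile,
    condition: WalkCondition,
    n_steps: int,
    geometry: MatGeometry = MatGeometry(),
    *,
    lead_in_frames: int = 4,
    seed: int = 0,
) -> np.ndarray:
    """Noise-free floating-point frame stack for one walk (pre-clipping).

    Exposes the raw physical signal so that clipping-independent
    properties (e.g. pressure-mass monotonicity in body weight) can be
    checked; :func:`simulate_walk` quantises, perturbs and clips this.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    cyc = profile.cadence_frames
    half = cyc // 2
    stance = max(2, int(round(0.6 * cyc)))
    onsets = [lead_in_frames + k * half for k in range(n_steps)]
    n_frames = onsets[-1] + stance + 2

    rows, cols = geometry.rows, geometry.cols
    frames = np.zeros((n_frames, rows, cols), dtype=np.float64)

    # peak cell pressure proportional to body weight (plus any carried load)
    peak = 2.0 * (profile.weight_kg + condition.load_g / 1000.0)
    peak *= condition.load_scale

    dr, dc = condition.load_cop_shift_cells
    # stance-phase envelopes: heel strikes first, forefoot pushes off last
    t = (np.arange(stance) + 0.5) / stance
    env = np.sin(np.pi * t)  # overall load envelope
    w_heel = env * np.clip(1.0 - 1.4 * t, 0.0, 1.0) * 2.2
    w_fore = env * np.clip(1.4 * t - 0.4, 0.0, 1.0) * 2.2

    for k, onset in enumerate(onsets):
        left = k % 2 == 0
        heel, fore = profile.template_left if left else profile.template_right
        side_scale = profile.asymmetry if left else 1.0
        lane = _LEFT_LANE_COL if left else _RIGHT_LANE_COL
        r0 = 8 + k * profile.stride_cells
        if r0 + 32 > rows or lane + 16 > cols:
            raise ValueError(
                f"step {k} footprint window exceeds mat bounds "
                f"(rows {r0}..{r0 + 32} of {rows})"
            )
        # carried load: shift the template inside its window
        patch_h = np.roll(heel, (dr, dc), axis=(0, 1)) if (dr or dc) else heel
        patch_f = np.roll(fore, (dr, dc), axis=(0, 1)) if (dr or dc) else fore
        for j in range(stance):
            patch = (w_heel[j] * patch_h + w_fore[j] * patch_f)
            frames[onset + j, r0:r0 + 32, lane:lane + 16] += (
                peak * side_scale * patch
            )
    return frames


def simulate_walk(
    profile: SubjectProfile,
    condition: WalkCondition = WalkCondition(),
    n_steps: int = 4,
    geometry: MatGeometry = MatGeometry(),
    noise_sd: float = 0.0,
    anomaly_rate: float = 0.0,
    seed: int = 0,
    **kwargs,
) -> PressureFrameSequence:
    """Simulate one traversal of the mat.

    Steps alternate left/right; each contact occupies ~60 % of its gait
    cycle.  ``noise_sd`` adds integer-rounded Gaussian noise to active
    cells; ``anomaly_rate`` is the per-frame probability of one isolated
    full-scale (255) single-cell spike.  Output values are clipped to the
    8-bit range, never wrapped.
    """
    frames = simulate_walk_float(profile, condition, n_steps, geometry,
                                 seed=seed, **kwargs)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        active = frames > 0
        noise = rng.normal(0.0, noise_sd, size=frames.shape)
        frames = frames + np.rint(noise) * active
    out = np.clip(np.rint(frames), 0, geometry.value_max).astype(np.uint8)
    if anomaly_rate > 0:
        for ti in range(out.shape[0]):
            if rng.random() < anomaly_rate:
                r = int(rng.integers(1, geometry.rows - 1))
                c = int(rng.integers(1, geometry.cols - 1))
                out[ti, r, c] = geometry.value_max
    return PressureFrameSequence(
        frames=out,
        subject_id=profile.subject_id,
        condition=condition.label,
        sample_rate_hz=geometry.sample_rate_hz,
    )


# ---------------------------------------------------------------------------
# cohort trial scheduling

_MAX_STEPS_PER_WALK = 11  # 11 contacts -> 10 average maps per traversal


def plan_round_walks(unit_steps: int) -> list[int]:
    """Step counts of the traversals needed for one round.

    A traversal of ``s`` contacts yields ``s - 1`` average maps ("unit
    steps" in the dataset-accounting sense), so a 40-unit-step round is
    four 11-contact traversals.
    """
    if unit_steps < 1:
        raise ValueError("unit_steps must be positive")
    plan = []
    remaining = unit_steps
    while remaining > 0:
        maps = min(_MAX_STEPS_PER_WALK - 1, remaining)
        plan.append(maps + 1)
        remaining -= maps
    return plan


def schedule_cohort_trials(
    profiles: Sequence[SubjectProfile],
    rounds_type1: int,
    rounds_type2: int,
    unit_steps_per_round: int,
    seed: int = 0,
    geometry: MatGeometry = MatGeometry(),
    noise_sd: float = 0.0,
    anomaly_rate: float = 0.0,
) -> list[PressureFrameSequence]:
    """Emit every traversal of a full cohort protocol.

    Per subject: ``rounds_type1`` unloaded rounds then ``rounds_type2``
    rounds carrying 500 g, each round sized to yield exactly
    ``unit_steps_per_round`` unit steps downstream.  Round ids are 1-based
    with Type II rounds numbered after Type I.
    """
    if rounds_type1 < 0 or rounds_type2 < 0:
        raise ValueError("round counts must be non-negative")
    walk_plan = plan_round_walks(unit_steps_per_round)
    sequences: list[PressureFrameSequence] = []
    trial_id = 0
    for profile in profiles:
        for round_id in range(1, rounds_type1 + rounds_type2 + 1):
            cond = (WalkCondition.type_i() if round_id <= rounds_type1
                    else WalkCondition.type_ii())
            for n_steps in walk_plan:
                walk_seed = (seed * 1_000_003
                             + profile.subject_id * 1009
                             + round_id * 101 + trial_id) % (2**31 - 1)
                seq = simulate_walk(
                    profile, cond, n_steps, geometry,
                    noise_sd=noise_sd, anomaly_rate=anomaly_rate,
                    seed=walk_seed,
                )
                seq.trial_id = trial_id
                seq.round_id = round_id
                sequences.append(seq)
                trial_id += 1
    return sequences


# ---------------------------------------------------------------------------
# persistence: one compressed container per run + CSV manifest


def save_trials(sequences: Sequence[PressureFrameSequence], out_dir: str | Path) -> Path:
    """Persist trials as ``trials.npz`` plus a ``manifest.csv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arrays = {f"trial_{s.trial_id:05d}": s.frames for s in sequences}
    np.savez_compressed(out / "trials.npz", **arrays)
    manifest = pd.DataFrame(
        [
            {
                "trial_id": s.trial_id,
                "subject_id": s.subject_id,
                "condition": s.condition,
                "round_id": s.round_id,
                "n_frames": s.n_frames,
                "sample_rate_hz": s.sample_rate_hz,
            }
            for s in sequences
        ]
    )
    manifest.to_csv(out / "manifest.csv", index=False)
    return out


def load_trials(in_dir: str | Path) -> list[PressureFrameSequence]:
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    out = []
    with np.load(in_dir / "trials.npz") as data:
        for rec in manifest.to_dict("records"):
            out.append(
                PressureFrameSequence(
                    frames=data[f"trial_{rec['trial_id']:05d}"],
                    subject_id=int(rec["subject_id"]),
                    condition=str(rec["condition"]),
                    trial_id=int(rec["trial_id"]),
                    round_id=int(rec["round_id"]),
                    sample_rate_hz=int(rec["sample_rate_hz"]),
                )
            )
    return out
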