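"""Procedural generation of labelled binary silhouette walking sequences.

A planar articulated walker (rigid thigh/shank/foot/torso/arm segments,
sinusoidal hip trajectories with the two legs in antiphase, a double-bump
knee-flexion profile peaked in swing) is rendered into binary masks as a
union of filled capsules, a torso capsule and a head disc.  Five gait
styles encode stylized sagittal-view signatures of the gait classes:

* ``normal`` — symmetric, upright, zero lean;
* ``diplegic`` — bilateral stiff knees, forward lean, short steps;
* ``hemiplegic`` — unilaterally reduced hip/knee excursion (stiff left leg);
* ``neuropathic`` — high-stepping (steppage) gait with elevated foot lift;
* ``parkinsonian`` — stooped, shuffling, markedly short quick steps.

Each style comes in two severity levels that move every deviating
parameter further from the normal preset.  These are *stylized kinematic
signatures*, not biomechanically calibrated models: the classes they
emulate are themselves simulations performed by healthy subjects.

A segmentation-error corruption mode (pixel flips, spurious blobs,
morphological erosion) emulates noisy background-subtraction silhouettes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import RenderError, ValidationError
from .io import (
    CLASS_LABELS,
    SilhouetteFrame,
    SilhouetteSequence,
    append_manifest_row,
    write_sequence,
)

# body proportions as fractions of body_height
_PROP = {
    "thigh": 0.26,
    "shank": 0.24,
    "torso": 0.36,
    "neck": 0.05,
    "head_r": 0.07,
    "upper_arm": 0.16,
    "forearm": 0.15,
    "foot": 0.09,
}

_DEFAULT_WIDTH_FRACTIONS = {
    "torso": 0.170,
    "thigh": 0.090,
    "shank": 0.065,
    "upper_arm": 0.055,
    "forearm": 0.045,
    "foot": 0.050,
    "neck": 0.060,
}


@dataclass
class GaitStyleParams:
    """Kinematic style of one walker.

    Angles in degrees, lengths in pixels.  ``shuffle`` in [0, 1] scales
    down foot clearance (knee swing bump and steppage lift) without
    touching the root translation, which is always
    ``phase * step_length * 2`` over a cycle.
    """

    cycle_frames: int = 30
    step_length: float = 42.0
    torso_lean: float = 0.0
    hip_amp_left: float = 25.0
    hip_amp_right: float = 25.0
    knee_amp_left: float = 50.0
    knee_amp_right: float = 50.0
    foot_lift_left: float = 0.0
    foot_lift_right: float = 0.0
    shuffle: float = 0.0
    cadence_jitter: float = 0.02
    limb_widths: dict = field(default_factory=dict)
    body_height: float = 100.0

    def __post_init__(self) -> None:
        if self.cycle_frames < 18:
            raise ValidationError("cycle_frames must be >= 18")
        if self.step_length <= 0:
            raise ValidationError("step_length must be positive")
        if not 0.0 <= self.shuffle <= 1.0:
            raise ValidationError("shuffle must lie in [0, 1]")
        for name in ("hip_amp_left", "hip_amp_right", "knee_amp_left", "knee_amp_right",
                     "foot_lift_left", "foot_lift_right"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        widths = {k: v * self.body_height for k, v in _DEFAULT_WIDTH_FRACTIONS.items()}
        widths.update(self.limb_widths)
        self.limb_widths = widths


@dataclass
class NoiseParams:
    """Segmentation-error corruption rates (all per frame unless noted)."""

    flip_rate: float = 0.0  # per-pixel Bernoulli flip probability
    blob_rate: float = 0.0  # expected spurious blobs per frame (Poisson)
    erosion_prob: float = 0.0  # probability of a 3x3 erosion pass
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.flip_rate, self.blob_rate, self.erosion_prob) < 0:
            raise ValidationError("noise rates must be >= 0")
        if self.flip_rate >= 0.05:
            raise ValidationError("flip_rate must be < 0.05")


@dataclass
class PoseFrame:
    """2D joint positions (px, ground at y=0, y increasing upward)."""

    joints: dict[str, tuple[float, float]]

    def segment_length(self, a: str, b: str) -> float:
        (xa, ya), (xb, yb) = self.joints[a], self.joints[b]
        return math.hypot(xb - xa, yb - ya)


# ---------------------------------------------------------------------------
# presets

_PRESETS: dict[tuple[str, int], dict] = {
    ("normal", 1): {},
    ("normal", 2): {},
    ("diplegic", 1): dict(cycle_frames=32, step_length=26, torso_lean=10,
                          hip_amp_left=16, hip_amp_right=16,
                          knee_amp_left=30, knee_amp_right=30, shuffle=0.15),
    ("diplegic", 2): dict(cycle_frames=32, step_length=18, torso_lean=18,
                          hip_amp_left=11, hip_amp_right=11,
                          knee_amp_left=18, knee_amp_right=18, shuffle=0.25),
    ("hemiplegic", 1): dict(step_length=32, torso_lean=2,
                            hip_amp_left=12, knee_amp_left=18),
    ("hemiplegic", 2): dict(step_length=26, torso_lean=4,
                            hip_amp_left=7, knee_amp_left=8),
    ("neuropathic", 1): dict(step_length=38, hip_amp_left=27, hip_amp_right=27,
                             knee_amp_left=65, knee_amp_right=65,
                             foot_lift_left=10, foot_lift_right=10),
    ("neuropathic", 2): dict(step_length=34, hip_amp_left=29, hip_amp_right=29,
                             knee_amp_left=78, knee_amp_right=78,
                             foot_lift_left=18, foot_lift_right=18),
    ("parkinsonian", 1): dict(cycle_frames=26, step_length=16, torso_lean=15,
                              hip_amp_left=9, hip_amp_right=9,
                              knee_amp_left=35, knee_amp_right=35, shuffle=0.55),
    ("parkinsonian", 2): dict(cycle_frames=24, step_length=10, torso_lean=24,
                              hip_amp_left=6, hip_amp_right=6,
                              knee_amp_left=28, knee_amp_right=28, shuffle=0.75),
}


def style_preset(class_label: str, severity: int = 1) -> GaitStyleParams:
    """Deterministic kinematic preset for a (class, severity) pair.

    Presets are pairwise distinguishable by construction and severity 2
    moves every deviating parameter further from the normal preset.
    """
    if class_label not in CLASS_LABELS:
        raise ValidationError(f"unknown gait class {class_label!r}")
    if severity not in (1, 2):
        raise ValidationError("severity must be 1 or 2")
    return GaitStyleParams(**_PRESETS[(class_label, severity)])


# ---------------------------------------------------------------------------
# kinematics


def _knee_profile(phi: float, knee_amp: float, clearance: float) -> float:
    """Double-bump knee flexion (degrees): small stance yield, large swing bump."""
    if phi < 0.6:
        return 0.2 * knee_amp * clearance * math.sin(math.pi * phi / 0.6) ** 2
    return knee_amp * clearance * math.sin(math.pi * (phi - 0.6) / 0.4) ** 2


def _lift_profile(phi: float, lift_px: float, clearance: float, leg_len: float) -> float:
    """Extra swing-phase hip flexion (radians) producing a steppage foot lift."""
    if phi < 0.6 or lift_px <= 0:
        return 0.0
    return (lift_px * clearance / leg_len) * math.sin(math.pi * (phi - 0.6) / 0.4)


def pose_at_phase(params: GaitStyleParams, phase: float) -> PoseFrame:
    """Joint positions at a cycle fraction ``phase`` in [0, 1).

    The two legs run in antiphase; horizontal root translation equals
    ``phase * step_length * 2`` within the cycle; maximum horizontal ankle
    separation occurs at phase 0 (double support) by construction.
    Deterministic in ``(params, phase)``.
    """
    H = params.body_height
    thigh, shank = _PROP["thigh"] * H, _PROP["shank"] * H
    leg_len = thigh + shank
    clearance = 1.0 - 0.7 * params.shuffle
    root_x = (phase % 1.0) * params.step_length * 2.0

    legs = {}
    for side, hip_amp, knee_amp, lift in (
        ("left", params.hip_amp_left, params.knee_amp_left, params.foot_lift_left),
        ("right", params.hip_amp_right, params.knee_amp_right, params.foot_lift_right),
    ):
        phi = (phase + (0.0 if side == "left" else 0.5)) % 1.0
        hip = math.radians(hip_amp) * math.cos(2 * math.pi * phi)
        hip += _lift_profile(phi, lift, clearance, leg_len)
        knee = math.radians(_knee_profile(phi, knee_amp, clearance))
        legs[side] = (hip, knee)

    # hip height: lowest ankle rests exactly on the ground line
    drops = {
        s: thigh * math.cos(h) + shank * math.cos(h - k) for s, (h, k) in legs.items()
    }
    hip_y = max(drops.values())
    joints: dict[str, tuple[float, float]] = {"hip": (root_x, hip_y)}
    foot_len = _PROP["foot"] * H
    for s, (h, k) in legs.items():
        kx = root_x + thigh * math.sin(h)
        ky = hip_y - thigh * math.cos(h)
        ax = kx + shank * math.sin(h - k)
        ay = ky - shank * math.cos(h - k)
        joints[f"knee_{s}"] = (kx, ky)
        joints[f"ankle_{s}"] = (ax, ay)
        joints[f"toe_{s}"] = (ax + foot_len, ay)

    lean = math.radians(params.torso_lean)
    torso = _PROP["torso"] * H
    neck = (root_x + torso * math.sin(lean), hip_y + torso * math.cos(lean))
    joints["neck"] = neck
    joints["shoulder"] = neck
    head_off = (_PROP["neck"] + _PROP["head_r"]) * H
    joints["head"] = (neck[0] + head_off * math.sin(lean), neck[1] + head_off * math.cos(lean))

    arm_amp = 0.5 * math.radians(0.5 * (params.hip_amp_left + params.hip_amp_right))
    ua, fa = _PROP["upper_arm"] * H, _PROP["forearm"] * H
    for s, sign in (("left", -1.0), ("right", 1.0)):
        # arms swing in antiphase with the same-side leg
        a = sign * arm_amp * math.cos(2 * math.pi * phase)
        ex = neck[0] + ua * math.sin(a)
        ey = neck[1] - ua * math.cos(a)
        wa = a + math.radians(20)  # constant elbow flexion, forearm forward
        joints[f"elbow_{s}"] = (ex, ey)
        joints[f"wrist_{s}"] = (ex + fa * math.sin(wa), ey - fa * math.cos(wa))
    return PoseFrame(joints)


# ---------------------------------------------------------------------------
# rasterization

_SEGMENTS = [
    ("hip", "knee_left", "thigh"),
    ("knee_left", "ankle_left", "shank"),
    ("ankle_left", "toe_left", "foot"),
    ("hip", "knee_right", "thigh"),
    ("knee_right", "ankle_right", "shank"),
    ("ankle_right", "toe_right", "foot"),
    ("hip", "neck", "torso"),
    ("neck", "head", "neck"),
    ("shoulder", "elbow_left", "upper_arm"),
    ("elbow_left", "wrist_left", "forearm"),
    ("shoulder", "elbow_right", "upper_arm"),
    ("elbow_right", "wrist_right", "forearm"),
]


def _world_to_image(pt: tuple[float, float], canvas_h: int) -> tuple[float, float]:
    """(x, y-up) world coordinates -> (row, col) with ground near the bottom."""
    x, y = pt
    return canvas_h - 6 - y, x


def _fill_capsule(mask: np.ndarray, p1, p2, radius: float) -> None:
    """Set mask pixels within ``radius`` of the segment p1-p2 (row/col coords)."""
    h, w = mask.shape
    r1, c1 = p1
    r2, c2 = p2
    rmin = max(0, int(math.floor(min(r1, r2) - radius - 1)))
    rmax = min(h - 1, int(math.ceil(max(r1, r2) + radius + 1)))
    cmin = max(0, int(math.floor(min(c1, c2) - radius - 1)))
    cmax = min(w - 1, int(math.ceil(max(c1, c2) + radius + 1)))
    if rmin > rmax or cmin > cmax:
        return
    rr, cc = np.meshgrid(
        np.arange(rmin, rmax + 1), np.arange(cmin, cmax + 1), indexing="ij"
    )
    dr, dc = r2 - r1, c2 - c1
    seg2 = dr * dr + dc * dc
    if seg2 == 0:
        t = np.zeros_like(rr, dtype=float)
    else:
        t = np.clip(((rr - r1) * dr + (cc - c1) * dc) / seg2, 0.0, 1.0)
    d2 = (rr - (r1 + t * dr)) ** 2 + (cc - (c1 + t * dc)) ** 2
    mask[rmin : rmax + 1, cmin : cmax + 1] |= (d2 <= radius * radius).astype(np.uint8)


def _check_fits(pose: PoseFrame, canvas: tuple[int, int], pad: float) -> None:
    """Joint centres must lie on the canvas (head with its full radius);
    limb thickness may clip at most a border pixel."""
    h, w = canvas
    for name, pt in pose.joints.items():
        r, c = _world_to_image(pt, h)
        margin = pad if name == "head" else 1.0
        if not (margin <= r <= h - 1 - margin and margin <= c <= w - 1 - margin):
            raise RenderError(
                f"joint {name} at image ({r:.0f}, {c:.0f}) outside {h}x{w} canvas"
            )


def render_silhouette(
    pose: PoseFrame, params: GaitStyleParams, canvas: tuple[int, int]
) -> SilhouetteFrame:
    """Rasterize a pose as a filled binary silhouette (single component)."""
    head_r = _PROP["head_r"] * params.body_height
    _check_fits(pose, canvas, pad=max(head_r, params.limb_widths["torso"] / 2))
    mask = np.zeros(canvas, dtype=np.uint8)
    h = canvas[0]
    for a, b, part in _SEGMENTS:
        _fill_capsule(
            mask,
            _world_to_image(pose.joints[a], h),
            _world_to_image(pose.joints[b], h),
            params.limb_widths[part] / 2.0,
        )
    _fill_capsule(mask, _world_to_image(pose.joints["head"], h),
                  _world_to_image(pose.joints["head"], h), head_r)
    return SilhouetteFrame(mask)


def render_skeleton(
    pose: PoseFrame, canvas: tuple[int, int], line_width: float = 2.0
) -> SilhouetteFrame:
    """Rasterize the segment graph as a thin binary polyline drawing."""
    if not 1.0 <= line_width <= 3.0:
        raise ValidationError("line_width must lie in [1, 3] px")
    _check_fits(pose, canvas, pad=line_width)
    mask = np.zeros(canvas, dtype=np.uint8)
    h = canvas[0]
    for a, b, _ in _SEGMENTS:
        _fill_capsule(
            mask,
            _world_to_image(pose.joints[a], h),
            _world_to_image(pose.joints[b], h),
            line_width / 2.0,
        )
    return SilhouetteFrame(mask)


# ---------------------------------------------------------------------------
# sequence and dataset generation


def _rng(*keys: int) -> np.random.Generator:
    """Deterministic substream derived from integer keys (documented hashing)."""
    return np.random.default_rng(np.random.SeedSequence(list(keys)))


def generate_sequence(
    params: GaitStyleParams,
    n_cycles: int,
    seed: int = 0,
    render_skeletons: bool = True,
) -> tuple[SilhouetteSequence, list[int], list[SilhouetteFrame]]:
    """Render ``n_cycles`` gait cycles of one walker.

    Returns the silhouette sequence, the exact ground-truth cycle boundary
    frame indices (``n_cycles + 1`` entries; multiples of ``cycle_frames``
    when ``cadence_jitter`` is zero) and the matching skeleton frames.
    Bit-reproducible under a fixed seed.
    """
    if n_cycles < 1:
        raise ValidationError("n_cycles must be >= 1")
    n = n_cycles * params.cycle_frames
    rng = _rng(seed, 0xC1C1E)
    inc = np.full(n, 1.0 / params.cycle_frames)
    if params.cadence_jitter > 0:
        inc *= 1.0 + params.cadence_jitter * rng.uniform(-1, 1, size=n)
        inc *= n_cycles / inc.sum()  # whole sequence spans exactly n_cycles
    phases = np.concatenate([[0.0], np.cumsum(inc)])
    boundaries = [
        int(np.searchsorted(phases, k - 1e-9)) for k in range(n_cycles)
    ] + [n]

    H = params.body_height
    margin = 0.65 * H
    canvas_h = int(math.ceil(1.05 * H)) + 12
    canvas_w = int(math.ceil(2 * margin + 2 * params.step_length * n_cycles))
    frames, skels = [], []
    for i in range(n):
        phase = phases[i]
        pose = pose_at_phase(params, phase % 1.0)
        # translate continuously across the canvas rather than per cycle
        dx = margin + phase * params.step_length * 2.0 - pose.joints["hip"][0]
        shifted = PoseFrame({k: (x + dx, y) for k, (x, y) in pose.joints.items()})
        frames.append(render_silhouette(shifted, params, (canvas_h, canvas_w)))
        if render_skeletons:
            skels.append(render_skeleton(shifted, (canvas_h, canvas_w)))
    seq = SilhouetteSequence(frames=frames)
    return seq, boundaries, skels


def corrupt(seq: SilhouetteSequence, noise: NoiseParams) -> SilhouetteSequence:
    """Apply segmentation-error corruption; deterministic under ``noise.seed``."""
    from scipy import ndimage

    rng = _rng(noise.seed, 0x0153)
    out = []
    for f in seq.frames:
        mask = f.mask.copy()
        if noise.erosion_prob > 0 and rng.random() < noise.erosion_prob:
            mask = ndimage.binary_erosion(mask, np.ones((3, 3))).astype(np.uint8)
        if noise.blob_rate > 0:
            for _ in range(rng.poisson(noise.blob_rate)):
                r = int(rng.integers(0, mask.shape[0]))
                c = int(rng.integers(0, mask.shape[1]))
                rad = int(rng.integers(1, 4))
                rr, cc = np.ogrid[: mask.shape[0], : mask.shape[1]]
                mask[(rr - r) ** 2 + (cc - c) ** 2 <= rad * rad] = 1
        if noise.flip_rate > 0:
            flips = rng.random(mask.shape) < noise.flip_rate
            mask = np.where(flips, 1 - mask, mask).astype(np.uint8)
        out.append(SilhouetteFrame(mask, f.index))
    return SilhouetteSequence(
        frames=out,
        subject_id=seq.subject_id,
        class_label=seq.class_label,
        severity=seq.severity,
        direction=seq.direction,
        fps=seq.fps,
        is_repetition=seq.is_repetition,
    )


_PERTURB_FIELDS = (
    "step_length", "torso_lean", "hip_amp_left", "hip_amp_right",
    "knee_amp_left", "knee_amp_right", "foot_lift_left", "foot_lift_right",
    "shuffle", "body_height",
)


def perturb_params(
    params: GaitStyleParams, rng: np.random.Generator, amount: float = 0.10
) -> GaitStyleParams:
    """Multiply each kinematic parameter by an independent U(1-a, 1+a) factor.

    Drawn once per subject, this induces a stable subject identity so that
    subject-wise cross-validation folds are meaningful.
    """
    changes = {}
    for name in _PERTURB_FIELDS:
        changes[name] = getattr(params, name) * rng.uniform(1 - amount, 1 + amount)
    changes["shuffle"] = float(np.clip(changes["shuffle"], 0.0, 1.0))
    changes["cycle_frames"] = max(
        18, int(round(params.cycle_frames * rng.uniform(1 - amount, 1 + amount)))
    )
    return replace(params, **changes, limb_widths={})


@dataclass
class GeneratedSequence:
    """One rendered sequence plus its generation ground truth."""

    sequence: SilhouetteSequence
    boundaries: list[int]
    skeletons: list[SilhouetteFrame]


def generate_cohort(
    n_subjects: int,
    classes: Sequence[str] = CLASS_LABELS,
    severities: Sequence[int] = (1, 2),
    directions: Sequence[str] = ("left_to_right", "right_to_left"),
    n_cycles: int = 3,
    noise: NoiseParams | None = None,
    seed: int = 0,
    render_skeletons: bool = False,
) -> list[GeneratedSequence]:
    """Generate an in-memory labelled cohort.

    One sequence per (subject, class, severity, direction); the normal
    class is emitted once per severity slot as well, for a uniform layout.
    Subject identity comes from a per-subject +-10% perturbation of every
    preset, drawn from a per-subject substream of ``seed``.
    """
    if n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    out = []
    for s in range(n_subjects):
        # one identity factor set per subject, applied to every class preset
        identity_rng = _rng(seed, s, 9999)
        ratios = {name: identity_rng.uniform(0.9, 1.1) for name in _PERTURB_FIELDS}
        cycle_ratio = identity_rng.uniform(0.9, 1.1)
        for ci, c in enumerate(classes):
            for sev in severities:
                base = style_preset(c, sev)
                changes = {
                    name: getattr(base, name) * ratios[name]
                    for name in _PERTURB_FIELDS
                }
                changes["shuffle"] = float(np.clip(changes["shuffle"], 0.0, 1.0))
                changes["cycle_frames"] = max(
                    18, int(round(base.cycle_frames * cycle_ratio))
                )
                styled = replace(base, **changes, limb_widths={})
                for d in directions:
                    sseed = int(
                        _rng(seed, s, ci, sev, 0 if d == "left_to_right" else 1)
                        .integers(0, 2**31 - 1)
                    )
                    seq, bounds, skels = generate_sequence(
                        styled, n_cycles, seed=sseed,
                        render_skeletons=render_skeletons,
                    )
                    seq = SilhouetteSequence(
                        frames=seq.frames,
                        subject_id=f"S{s + 1:02d}",
                        class_label=c,
                        severity=sev,
                        direction="left_to_right",
                        fps=30.0,
                    )
                    if d == "right_to_left":
                        seq = seq.mirrored()
                        skels = [
                            SilhouetteFrame(f.mask[:, ::-1].copy(), f.index)
                            for f in skels
                        ]
                    if noise is not None:
                        seq = corrupt(seq, replace(noise, seed=sseed ^ noise.seed))
                    out.append(GeneratedSequence(seq, bounds, skels))
    return out


def generate_dataset(
    out_dir: str | Path,
    n_subjects: int,
    classes: Sequence[str] = CLASS_LABELS,
    severities: Sequence[int] = (1, 2),
    directions: Sequence[str] = ("left_to_right", "right_to_left"),
    n_cycles: int = 3,
    noise: NoiseParams | None = None,
    seed: int = 0,
    write_skeletons: bool = False,
) -> Path:
    """Write a synthetic PNG-stack dataset plus CSV manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    if manifest.exists():
        manifest.unlink()
    cohort = generate_cohort(
        n_subjects, classes, severities, directions, n_cycles, noise, seed,
        render_skeletons=write_skeletons,
    )
    for item in cohort:
        seq = item.sequence
        name = f"{seq.subject_id}_{seq.class_label}_s{seq.severity}_{seq.direction}"
        d = out_dir / name
        write_sequence(seq, d)
        append_manifest_row(manifest, seq, d)
        np.savetxt(d / "boundaries.csv", np.asarray(item.boundaries, int),
                   fmt="%d", header="true_cycle_boundary", comments="")
        if write_skeletons:
            skel_dir = out_dir / (name + "_skel")
            write_sequence(SilhouetteSequence(frames=item.skeletons), skel_dir)
    return manifest
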