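"""Reading, writing and normalizing binary silhouette sequences.

A sequence is a directory of single-channel PNG frames (one frame per file,
lexicographic filename order) described by a row of a CSV manifest with
columns ``sequence_dir,subject_id,class_label,severity,direction,fps`` and
an optional ``is_repetition`` flag.

Masks are kept as ``uint8`` arrays containing only {0, 1}.  Alignment for
representation/feature extraction follows the usual gait-energy-image
convention: the silhouette is isotropically rescaled so its height spans a
fixed fraction of a square canvas, anchored at the bottom margin and
horizontally centred on its foreground centroid.  Cycle detection must run
on the *unaligned* masks, because alignment removes the feet-distance
signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .errors import FormatError, InputError, NormalizationError, ValidationError

logger = logging.getLogger(__name__)

#: The five gait classes, in the fixed order used throughout the package.
CLASS_LABELS = ("diplegic", "hemiplegic", "neuropathic", "normal", "parkinsonian")

#: Allowed walking directions.
DIRECTIONS = ("left_to_right", "right_to_left")

MANIFEST_COLUMNS = [
    "sequence_dir",
    "subject_id",
    "class_label",
    "severity",
    "direction",
    "fps",
    "is_repetition",
]


@dataclass
class SilhouetteFrame:
    """One binary silhouette mask (1 = foreground) at position ``index``."""

    mask: np.ndarray
    index: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise FormatError("silhouette mask must contain only {0, 1}")
        self.mask = self.mask.astype(np.uint8)

    @property
    def foreground_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class SilhouetteSequence:
    """Ordered silhouette frames plus the manifest metadata."""

    frames: list[SilhouetteFrame]
    subject_id: str = ""
    class_label: str = "normal"
    severity: int | None = None
    direction: str = "left_to_right"
    fps: float = 30.0
    is_repetition: bool = False

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValidationError(f"unknown class label {self.class_label!r}")
        if self.direction not in DIRECTIONS:
            raise ValidationError(f"unknown direction {self.direction!r}")
        shapes = {f.mask.shape for f in self.frames}
        if len(shapes) > 1:
            raise FormatError(f"inconsistent frame dimensions: {sorted(shapes)}")
        for i, f in enumerate(self.frames):
            f.index = i

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def masks(self) -> np.ndarray:
        """All masks stacked as (n_frames, rows, cols)."""
        return np.stack([f.mask for f in self.frames])

    def mirrored(self) -> "SilhouetteSequence":
        """Horizontally mirrored copy with the direction label flipped."""
        other = DIRECTIONS[1 - DIRECTIONS.index(self.direction)]
        return SilhouetteSequence(
            frames=[SilhouetteFrame(f.mask[:, ::-1].copy(), f.index) for f in self.frames],
            subject_id=self.subject_id,
            class_label=self.class_label,
            severity=self.severity,
            direction=other,
            fps=self.fps,
            is_repetition=self.is_repetition,
        )

    def canonical(self) -> "SilhouetteSequence":
        """The sequence in canonical left-to-right orientation."""
        return self if self.direction == "left_to_right" else self.mirrored()


@dataclass
class NormalizedFrame:
    """A silhouette resampled onto a fixed square canvas.

    ``scale`` is the isotropic rescale ratio applied to the tight bounding
    box; ``offset`` is the (row, col) translation of the box's top-left
    corner on the canvas.
    """

    mask: np.ndarray
    scale: float = 1.0
    offset: tuple[int, int] = (0, 0)


def binarize(image: np.ndarray) -> np.ndarray:
    """Threshold an image at half of its representable maximum.

    Integer images use half of the dtype maximum, float images 0.5; the
    operation is involutive on already-binary input.
    """
    arr = np.asarray(image)
    if arr.ndim == 3:  # collapse colour channels
        arr = arr.mean(axis=-1)
    if np.issubdtype(arr.dtype, np.integer):
        thresh = np.iinfo(arr.dtype).max / 2.0
    else:
        thresh = 0.5
    # uint8 {0,1} masks must stay fixed: treat max<=1 as already binary
    if np.issubdtype(arr.dtype, np.integer) and arr.max(initial=0) <= 1:
        return arr.astype(np.uint8)
    return (arr.astype(np.float64) > thresh).astype(np.uint8)


def read_sequence(dir_path: str | Path, manifest_entry: Mapping | None = None) -> SilhouetteSequence:
    """Read a PNG frame stack into a :class:`SilhouetteSequence`.

    Frames are ordered lexicographically by filename (``f_10.png`` sorts
    before ``f_2.png``; zero-pad filenames to get numeric order).  Pixel
    values are binarized at half the representable maximum.  All-zero
    frames are retained with a logged warning.
    """
    dir_path = Path(dir_path)
    if not dir_path.is_dir():
        raise InputError(f"sequence directory not found: {dir_path}")
    files = sorted(p for p in dir_path.iterdir() if p.suffix.lower() in {".png", ".pgm", ".bmp"})
    if not files:
        raise InputError(f"no image files in {dir_path}")
    frames = []
    for i, p in enumerate(files):
        mask = binarize(iio.imread(p))
        if mask.sum() == 0:
            logger.warning("frame %s is empty (all background); retained", p.name)
        frames.append(SilhouetteFrame(mask, i))
    shapes = {f.mask.shape for f in frames}
    if len(shapes) > 1:
        raise FormatError(f"inconsistent frame dimensions in {dir_path}: {sorted(shapes)}")
    meta = {} if manifest_entry is None else dict(manifest_entry)
    severity = meta.get("severity", None)
    if severity in ("", None) or (isinstance(severity, float) and np.isnan(severity)):
        severity = None
    else:
        severity = int(severity)
    return SilhouetteSequence(
        frames=frames,
        subject_id=str(meta.get("subject_id", dir_path.name)),
        class_label=str(meta.get("class_label", "normal")),
        severity=severity,
        direction=str(meta.get("direction", "left_to_right")),
        fps=float(meta.get("fps", 30.0)),
        is_repetition=bool(int(meta.get("is_repetition", 0) or 0)),
    )


def write_sequence(
    seq: SilhouetteSequence,
    dir_path: str | Path,
    manifest_path: str | Path | None = None,
) -> Path:
    """Write one PNG per frame (zero-padded names) and a manifest row.

    Round trip is bit exact: ``read_sequence(write_sequence(s))`` recovers
    the masks of ``s``.
    """
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    for i, f in enumerate(seq.frames):
        iio.imwrite(dir_path / f"{i:06d}.png", (f.mask * 255).astype(np.uint8))
    if manifest_path is not None:
        append_manifest_row(manifest_path, seq, dir_path)
    return dir_path


def append_manifest_row(manifest_path: str | Path, seq: SilhouetteSequence, dir_path: Path) -> None:
    manifest_path = Path(manifest_path)
    row = pd.DataFrame(
        [
            {
                "sequence_dir": str(dir_path),
                "subject_id": seq.subject_id,
                "class_label": seq.class_label,
                "severity": "" if seq.severity is None else seq.severity,
                "direction": seq.direction,
                "fps": seq.fps,
                "is_repetition": int(seq.is_repetition),
            }
        ],
        columns=MANIFEST_COLUMNS,
    )
    header = not manifest_path.exists()
    row.to_csv(manifest_path, mode="a", header=header, index=False)


def read_manifest(manifest_path: str | Path) -> pd.DataFrame:
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise InputError(f"manifest not found: {manifest_path}")
    df = pd.read_csv(manifest_path, dtype={"subject_id": str}, keep_default_na=False)
    missing = set(MANIFEST_COLUMNS[:6]) - set(df.columns)
    if missing:
        raise FormatError(f"manifest missing columns: {sorted(missing)}")
    if "is_repetition" not in df.columns:
        df["is_repetition"] = 0
    return df


def load_dataset(manifest_path: str | Path) -> list[SilhouetteSequence]:
    """Read every sequence listed in a manifest."""
    df = read_manifest(manifest_path)
    root = Path(manifest_path).parent
    out = []
    for _, row in df.iterrows():
        d = Path(row["sequence_dir"])
        if not d.is_absolute():
            d = root / d
        out.append(read_sequence(d, row))
    return out


def clean_frame(frame: SilhouetteFrame) -> SilhouetteFrame:
    """Keep the largest 4-connected component and fill enclosed holes.

    Robustness step against segmentation errors (spurious blobs, interior
    holes).  All-zero masks are returned unchanged with a warning.  Never
    increases the number of connected components.
    """
    mask = frame.mask
    if mask.sum() == 0:
        logger.warning("clean_frame: empty mask at frame %d left unchanged", frame.index)
        return SilhouetteFrame(mask.copy(), frame.index)
    labels, n = measure.label(mask, connectivity=1, return_num=True)
    if n > 1:
        largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
        mask = (labels == largest).astype(np.uint8)
    filled = ndimage.binary_fill_holes(mask).astype(np.uint8)
    return SilhouetteFrame(filled, frame.index)


def normalize_frame(
    frame: SilhouetteFrame,
    canvas_side: int = 224,
    height_fraction: float = 0.9,
) -> NormalizedFrame:
    """Rescale and place a silhouette on a fixed square canvas.

    The tight foreground bounding box is isotropically rescaled (nearest
    neighbour) so its height equals ``round(height_fraction * canvas_side)``,
    then placed with its bottom at the canvas bottom margin and its
    foreground centroid on the canvas centre column (within half a pixel).
    Re-running on an already-normalized frame is the identity.
    """
    mask = frame.mask
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise NormalizationError("cannot normalize an empty frame")
    r0, r1 = rows.min(), rows.max()
    c0, c1 = cols.min(), cols.max()
    crop = mask[r0 : r1 + 1, c0 : c1 + 1]
    bh, bw = crop.shape
    th = int(round(height_fraction * canvas_side))
    scale = th / bh
    if bh == th:
        resized = crop
        scale = 1.0
    else:
        tw = max(1, int(round(bw * scale)))
        ri = np.clip(np.floor((np.arange(th) + 0.5) / scale), 0, bh - 1).astype(int)
        ci = np.clip(np.floor((np.arange(tw) + 0.5) / (tw / bw)), 0, bw - 1).astype(int)
        # pin the edge samples so the resampled box stays tight (keeps
        # achieved height exactly th, which makes normalization idempotent)
        ri[0], ri[-1] = 0, bh - 1
        ci[0], ci[-1] = 0, bw - 1
        resized = crop[np.ix_(ri, ci)]
    th_, tw_ = resized.shape
    margin = int(round((1.0 - height_fraction) * canvas_side / 2.0))
    top = canvas_side - margin - th_
    fg_cols = np.nonzero(resized)[1]
    centroid = float(fg_cols.mean())
    centre = (canvas_side - 1) / 2.0
    left = int(round(centre - centroid))
    canvas = np.zeros((canvas_side, canvas_side), dtype=np.uint8)
    # clip the source region if an unusually wide silhouette overhangs
    src_c0 = max(0, -left)
    src_c1 = min(tw_, canvas_side - left)
    src_r0 = max(0, -top)
    src_r1 = min(th_, canvas_side - top)
    if src_c1 <= src_c0 or src_r1 <= src_r0:
        raise NormalizationError("silhouette does not fit on canvas")
    canvas[top + src_r0 : top + src_r1, left + src_c0 : left + src_c1] = resized[
        src_r0:src_r1, src_c0:src_c1
    ]
    return NormalizedFrame(canvas, scale=scale, offset=(top, left))


def normalize_many(
    frames: Iterable[SilhouetteFrame],
    canvas_side: int = 224,
    height_fraction: float = 0.9,
) -> list[NormalizedFrame]:
    return [normalize_frame(f, canvas_side, height_fraction) for f in frames]
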