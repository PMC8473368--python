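"""Averaged gait representations: gait energy image (GEI) and skeleton
energy image (SEI).

Both are the pixel-wise arithmetic mean of N aligned binary frames,

    E(x, y) = (1/N) * sum_i B_i(x, y),

yielding one grey-scale image on [0, 1] per gait cycle (or per group of
cycles).  The GEI averages silhouettes, the SEI the corresponding thin
skeleton rasterizations; the operator is identical and cannot tell the
two apart, so the caller declares the kind.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import FormatError, ValidationError
from .cycles import GaitCycle
from .io import NormalizedFrame, SilhouetteSequence, normalize_frame


@dataclass
class GaitRepresentation:
    """A grey-scale averaged gait image on [0, 1]."""

    image: np.ndarray
    kind: str = "GEI"
    n_frames: int = 0
    source_cycles: list = field(default_factory=list)


def _average(frames: Sequence[NormalizedFrame], kind: str) -> GaitRepresentation:
    if len(frames) == 0:
        raise ValidationError("cannot average zero frames")
    shapes = {f.mask.shape for f in frames}
    if len(shapes) > 1:
        raise FormatError(f"frame dimension mismatch: {sorted(shapes)}")
    stack = np.stack([f.mask.astype(np.float64) for f in frames])
    return GaitRepresentation(image=stack.mean(axis=0), kind=kind, n_frames=len(frames))


def compute_gei(frames: Sequence[NormalizedFrame]) -> GaitRepresentation:
    """Gait energy image: mean of N aligned binary silhouettes."""
    return _average(frames, "GEI")


def compute_sei(skeleton_frames: Sequence[NormalizedFrame]) -> GaitRepresentation:
    """Skeleton energy image: the same mean over skeleton rasterizations."""
    return _average(skeleton_frames, "SEI")


def representation_over_cycle(
    seq: SilhouetteSequence,
    cycle: GaitCycle,
    kind: str = "GEI",
    canvas_side: int = 224,
    height_fraction: float = 0.9,
) -> GaitRepresentation:
    """Normalize frames ``cycle.start..cycle.end`` (inclusive) and average them."""
    if cycle.end >= len(seq):
        raise ValidationError("cycle extends past the end of the sequence")
    frames = [
        normalize_frame(seq.frames[i], canvas_side, height_fraction)
        for i in range(cycle.start, cycle.end + 1)
    ]
    rep = _average(frames, kind)
    rep.source_cycles = [(cycle.start, cycle.end)]
    return rep


def export_representation(rep: GaitRepresentation, out_prefix: str | Path) -> dict:
    """Write an 8-bit PNG (``round(255 * value)``) plus a lossless NPZ."""
    import imageio.v3 as iio

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    png = out_prefix.with_suffix(".png")
    npz = out_prefix.with_suffix(".npz")
    iio.imwrite(png, np.round(255 * rep.image).astype(np.uint8))
    np.savez_compressed(npz, image=rep.image, kind=rep.kind, n_frames=rep.n_frames)
    return {"png": str(png), "npz": str(npz)}
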