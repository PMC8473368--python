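"""Gait-cycle segmentation and key-frame selection.

The horizontal separation between the feet, measured frame by frame,
oscillates with two maxima per stride (one per double-support instant).
A gait cycle is the span between three consecutive maxima of that
signal.  Within each cycle, nine key frames are selected at fixed cycle
fractions: the stance phase ends at 60% of the cycle and is divided into
five equal portions, the swing phase into three, so the fractions are

    0, 0.12, 0.24, 0.36, 0.48, 0.60, 11/15, 13/15, 1.

Key frame #1 is the first peak, #6 the stance-to-swing transition and #9
the closing peak.  The 60% transition is the healthy-gait constant and is
applied to every class.

Cycle detection must run on raw (unaligned) masks: height/centroid
alignment removes the very signal being measured.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks

from .errors import CycleDetectionError, ValidationError
from .io import SilhouetteSequence

#: The nine cycle fractions of the key frames (stance = first 60% in five
#: equal portions; swing = last 40% in three).
KEY_FRAME_FRACTIONS = (
    0.0, 0.12, 0.24, 0.36, 0.48, 0.60, 0.60 + 0.40 / 3, 0.60 + 0.80 / 3, 1.0
)


@dataclass
class FeetDistanceSignal:
    """Per-frame horizontal feet separation in px (smoothed).

    ``raw`` keeps the unsmoothed values: edge-truncated smoothing biases
    the first/last samples low, so boundary-peak checks consult it.
    """

    values: np.ndarray
    smoothing_window: int = 5
    raw: np.ndarray | None = None


@dataclass
class GaitCycle:
    """A cycle spanning three consecutive feet-distance peaks."""

    start: int
    mid: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.mid < self.end:
            raise ValidationError("cycle peaks must satisfy start < mid < end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class KeyFrameSet:
    """The 9 selected frame indices of one cycle and the fractions used."""

    indices: tuple[int, ...]
    fractions: tuple[float, ...] = KEY_FRAME_FRACTIONS


def feet_distance_signal(
    seq: SilhouetteSequence,
    band_fraction: float = 0.15,
    smooth_window: int = 5,
) -> FeetDistanceSignal:
    """Horizontal foreground span in the bottom band of each silhouette.

    For each frame, the foreground pixels whose row lies in the bottom
    ``band_fraction`` of the silhouette's bounding box are collected and
    the span ``max column - min column`` is taken, then smoothed with a
    centred, edge-truncated moving average of ``smooth_window`` frames.
    Empty frames (or empty bands) yield 0.
    """
    if len(seq) == 0:
        raise ValidationError("empty sequence")
    raw = np.zeros(len(seq), dtype=float)
    for i, frame in enumerate(seq.frames):
        rows, cols = np.nonzero(frame.mask)
        if rows.size == 0:
            continue
        r1 = rows.max()
        r0 = rows.min()
        band_top = r1 - band_fraction * (r1 - r0 + 1)
        sel = cols[rows >= band_top]
        if sel.size:
            raw[i] = float(sel.max() - sel.min())
    if smooth_window > 1:
        if smooth_window % 2 == 0:
            raise ValidationError("smooth_window must be odd")
        half = smooth_window // 2
        smoothed = np.empty_like(raw)
        for i in range(raw.size):
            lo, hi = max(0, i - half), min(raw.size, i + half + 1)
            smoothed[i] = raw[lo:hi].mean()
    else:
        smoothed = raw
    return FeetDistanceSignal(values=smoothed, smoothing_window=smooth_window, raw=raw)


def estimate_period(values: np.ndarray) -> float | None:
    """Dominant period (frames) from the first autocorrelation peak, if any."""
    x = np.asarray(values, float) - np.mean(values)
    if x.size < 6 or np.allclose(x, 0):
        return None
    acf = np.correlate(x, x, mode="full")[x.size - 1 :]
    acf /= acf[0]
    peaks, _ = find_peaks(acf[1:])
    if peaks.size == 0:
        return None
    return float(peaks[0] + 1)


def detect_peaks(
    signal: FeetDistanceSignal,
    min_separation: int | None = None,
    min_prominence: float | None = None,
) -> list[int]:
    """Locations of the feet-distance maxima.

    Defaults: prominence = 0.2 x signal range; separation = 0.25 x the
    autocorrelation-estimated period.  Boundary samples can qualify as
    peaks (the signal is padded below its minimum before peak finding),
    because walking sequences routinely start and end at double support.
    Plateau peaks report the plateau centre, ties to the lower index.
    """
    values = np.asarray(signal.values, float)
    if values.size < 3:
        raise CycleDetectionError("signal too short for peak detection")
    rng = float(values.max() - values.min())
    if rng == 0:
        raise CycleDetectionError("constant feet-distance signal: no peaks")
    if min_prominence is None:
        min_prominence = 0.2 * rng
    if min_separation is None:
        period = estimate_period(values)
        min_separation = max(1, int(round(0.25 * period))) if period else 1
    pad = values.min() - max(rng, 1.0)
    padded = np.concatenate([[pad], values, [pad]])
    locs, props = find_peaks(
        padded,
        prominence=min_prominence,
        distance=max(1, min_separation),
        plateau_size=1,
    )
    centres = (props["left_edges"] + props["right_edges"]) // 2
    peaks = sorted(int(c) - 1 for c in centres)
    # a boundary sample only counts as a peak if it is nearly as high as
    # the global maximum (sequences that stop mid-rise have no peak there);
    # judged on the unsmoothed signal when available, since truncated
    # smoothing biases the end samples low
    ref = signal.raw if signal.raw is not None else values
    cutoff = ref.max() - 0.2 * (ref.max() - ref.min())
    peaks = [p for p in peaks if 0 < p < values.size - 1 or ref[p] >= cutoff]
    if len(peaks) < 3:
        raise CycleDetectionError(
            f"found {len(peaks)} feet-distance peaks; at least 3 are needed "
            f"to delimit one gait cycle (signal length {values.size})"
        )
    return peaks


def segment_cycles(peaks: list[int]) -> list[GaitCycle]:
    """Pair consecutive peak triples into non-overlapping gait cycles.

    Cycle j spans peaks (2j, 2j+1, 2j+2); a trailing unpaired peak is
    left unused.
    """
    if len(peaks) < 3:
        raise CycleDetectionError("need at least 3 peaks to segment a cycle")
    cycles = []
    j = 0
    while 2 * j + 2 < len(peaks):
        cycles.append(GaitCycle(peaks[2 * j], peaks[2 * j + 1], peaks[2 * j + 2]))
        j += 1
    return cycles


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def select_key_frames(cycle: GaitCycle) -> KeyFrameSet:
    """The 9 key-frame indices of a cycle at the fixed cycle fractions.

    ``index_i = start + round_half_up(fraction_i * (end - start))``; the
    first/last key frames coincide with the delimiting peaks and key
    frame #6 marks the 60% stance-to-swing transition.  Cycles spanning
    fewer than 9 frames are rejected.
    """
    length = cycle.length
    if length + 1 < 9:
        raise ValidationError(
            f"cycle of {length + 1} frames is too short for 9 key frames"
        )
    indices = tuple(
        cycle.start + _round_half_up(f * length) for f in KEY_FRAME_FRACTIONS
    )
    return KeyFrameSet(indices=indices)


def extract_key_frame_sets(
    seq: SilhouetteSequence,
    band_fraction: float = 0.15,
    smooth_window: int = 5,
) -> tuple[list[GaitCycle], list[KeyFrameSet], FeetDistanceSignal]:
    """Convenience pipeline: signal -> peaks -> cycles -> key frames."""
    signal = feet_distance_signal(seq, band_fraction, smooth_window)
    peaks = detect_peaks(signal)
    cycles = [c for c in segment_cycles(peaks) if c.length + 1 >= 9]
    if not cycles:
        raise CycleDetectionError("no cycle long enough for 9 key frames")
    return cycles, [select_key_frames(c) for c in cycles], signal


def key_frame_report(
    seq: SilhouetteSequence,
    cycles: list[GaitCycle],
    keyframes: list[KeyFrameSet],
    signal: FeetDistanceSignal,
    out_prefix: str | Path,
) -> dict:
    """Serialize the feet-distance signal with key-frame markers (CSV + PNG).

    Returns a record with the marked frame indices (shared cycle
    boundaries counted once).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    marked = sorted({i for ks in keyframes for i in ks.indices})
    df = pd.DataFrame(
        {
            "frame": np.arange(signal.values.size),
            "feet_distance": signal.values,
            "is_key_frame": np.isin(np.arange(signal.values.size), marked).astype(int),
        }
    )
    csv_path = out_prefix.with_suffix(".csv")
    df.to_csv(csv_path, index=False)
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(df["frame"], df["feet_distance"], lw=1)
    if marked:
        ax.plot(marked, signal.values[marked], "ro", ms=4, label="key frames")
        ax.legend()
    ax.set_xlabel("frame")
    ax.set_ylabel("feet distance (px)")
    fig.tight_layout()
    png_path = out_prefix.with_suffix(".png")
    fig.savefig(png_path, dpi=100)
    plt.close(fig)
    return {
        "marked_frames": marked,
        "n_cycles": len(cycles),
        "csv": str(csv_path),
        "figure": str(png_path),
    }
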