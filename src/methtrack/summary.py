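"""Group-level summary tracks: mean, frequency, segmented frequency, difference.

The mean track averages per-bin intensity over a sample group.  The
simple frequency track reports, per bin, the fraction of samples whose
intensity exceeds a threshold (default 2 — in a typical
methylation-capture cohort most normalized bins sit below 2, so
recurrent exceedance marks a consistently methylated position).  The
segmented frequency (segFreq) applies a per-sample run-based
segmentation first, which suppresses isolated noisy bins:

  i.   binarize the sample's track at intensity >= 1;
  ii.  find the runs of 1s;
  iii. bridge runs separated by exactly one empty bin (<= 200 bp at
       100-bp bins);
  iv.  delete any remaining single-bin run whose intensity is below 3.

A sample then counts toward a bin's segFreq only where its mask is 1
and its intensity exceeds 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .track_io import BinnedTrack

__all__ = [
    "SegmentationMask",
    "SummaryTrack",
    "group_mean_track",
    "simple_frequency",
    "segment_track",
    "segmented_frequency",
    "difference_track",
]


@dataclass
class SegmentationMask:
    """Binary per-bin mask derived from a single sample's track."""

    sample_id: str
    masks: dict[str, np.ndarray]  # values in {0, 1}


@dataclass
class SummaryTrack:
    kind: str  # mean | simple_freq | seg_freq | difference
    group: str
    genome: object
    bin_size: int
    values: dict[str, np.ndarray]


def _check_group(tracks: Sequence[BinnedTrack]) -> BinnedTrack:
    if not tracks:
        raise ValueError("need at least one track")
    layout = tracks[0]
    for t in tracks[1:]:
        if not layout.same_layout(t):
            raise ValueError(f"track {t.sample_id!r} has a different bin layout")
    return layout


def group_mean_track(tracks: Sequence[BinnedTrack], group: str = "group") -> SummaryTrack:
    layout = _check_group(tracks)
    values = {
        c: np.mean([t.values[c] for t in tracks], axis=0) for c in layout.values
    }
    return SummaryTrack("mean", group, layout.genome, layout.bin_size, values)


def simple_frequency(
    tracks: Sequence[BinnedTrack],
    threshold: float = 2.0,
    group: str = "group",
    as_counts: bool = False,
) -> SummaryTrack:
    """Per-bin fraction (or count) of samples strictly above ``threshold``."""
    layout = _check_group(tracks)
    denom = 1.0 if as_counts else float(len(tracks))
    values = {
        c: np.sum([t.values[c] > threshold for t in tracks], axis=0) / denom
        for c in layout.values
    }
    return SummaryTrack("simple_freq", group, layout.genome, layout.bin_size, values)


def _segment_vector(vec: np.ndarray) -> np.ndarray:
    binary = (vec >= 1).astype(np.int8)
    if len(binary) >= 3:
        # bridge single-bin gaps between runs of 1s
        gaps = (binary[1:-1] == 0) & (binary[:-2] == 1) & (binary[2:] == 1)
        bridged = binary.copy()
        bridged[1:-1][gaps] = 1
    else:
        bridged = binary.copy()
    # delete singleton runs with original intensity < 3
    padded = np.concatenate(([0], bridged, [0]))
    starts = np.nonzero(np.diff(padded) == 1)[0]
    ends = np.nonzero(np.diff(padded) == -1)[0]
    for s, e in zip(starts, ends):
        if e - s == 1 and vec[s] < 3:
            bridged[s] = 0
    return bridged


def segment_track(track: BinnedTrack) -> SegmentationMask:
    """Run-based segmentation of one sample's track (steps i-iv above)."""
    masks = {c: _segment_vector(v) for c, v in track.values.items()}
    return SegmentationMask(track.sample_id, masks)


def segmented_frequency(
    tracks: Sequence[BinnedTrack],
    count_threshold: float = 1.0,
    group: str = "group",
    as_counts: bool = False,
) -> SummaryTrack:
    """segFreq: frequency of (mask == 1 and intensity > ``count_threshold``)."""
    layout = _check_group(tracks)
    denom = 1.0 if as_counts else float(len(tracks))
    values: dict[str, np.ndarray] = {}
    masks = [segment_track(t) for t in tracks]
    for c in layout.values:
        hits = [
            (m.masks[c] == 1) & (t.values[c] > count_threshold)
            for t, m in zip(tracks, masks)
        ]
        values[c] = np.sum(hits, axis=0) / denom
    return SummaryTrack("seg_freq", group, layout.genome, layout.bin_size, values)


def difference_track(summary_A: SummaryTrack, summary_B: SummaryTrack) -> SummaryTrack:
    """Signed per-bin difference A - B between two same-kind summaries."""
    if summary_A.kind != summary_B.kind:
        raise ValueError(
            f"cannot subtract {summary_B.kind!r} track from {summary_A.kind!r} track"
        )
    if summary_A.values.keys() != summary_B.values.keys() or any(
        len(summary_A.values[c]) != len(summary_B.values[c]) for c in summary_A.values
    ):
        raise ValueError("summaries have different bin layouts")
    values = {c: summary_A.values[c] - summary_B.values[c] for c in summary_A.values}
    return SummaryTrack(
        "difference",
        f"{summary_A.group}-{summary_B.group}",
        summary_A.genome,
        summary_A.bin_size,
        values,
    )
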