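"""Depth normalization of binned methylation tracks.

Two schemes are supported:

* **linear** — per-bin counts are rescaled by the library size so that
  tracks of different sequencing depth become comparable:
  ``N_i = U_i * N_bin / N_U`` where ``U_i`` is the raw count in bin i,
  ``N_U`` the total number of unique mapped reads and ``N_bin`` the
  total number of bins in the genome.  A library whose reads all fall
  in counted bins then has genome-wide mean intensity exactly 1.

* **quantile** — one group of samples serves as the reference
  distribution; every value of the target group is replaced by the
  reference quantile at its own empirical quantile,
  ``x -> F_ref^{-1}(F_target(x))``.  Both empirical distributions are
  pooled over all bins of all samples in the respective group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .track_io import BinnedTrack

__all__ = [
    "NormalizationParams",
    "linear_normalize",
    "quantile_normalize",
]


@dataclass(frozen=True)
class NormalizationParams:
    method: str = "linear"
    reference_group: str | None = None

    def __post_init__(self) -> None:
        if self.method not in ("linear", "quantile"):
            raise ValueError(f"unknown normalization method {self.method!r}")
        if self.method == "quantile" and self.reference_group is None:
            raise ValueError("quantile normalization requires a reference group")


def linear_normalize(
    track: BinnedTrack, total_unique_reads: float | None = None
) -> BinnedTrack:
    """Rescale raw counts to mean-per-bin intensity units.

    ``total_unique_reads`` overrides the library size recorded on the
    track (useful when the library includes reads mapped outside the
    analyzed chromosomes).
    """
    if track.normalized:
        raise ValueError(f"track {track.sample_id!r} is already normalized")
    n_u = track.total_unique_reads if total_unique_reads is None else total_unique_reads
    if n_u is None or n_u <= 0:
        raise ValueError(
            f"track {track.sample_id!r}: total unique read count must be positive"
        )
    n_bin = track.genome.total_bins(track.bin_size)
    factor = n_bin / n_u
    out = track.copy()
    out.values = {c: v * factor for c, v in track.values.items()}
    out.normalized = True
    return out


def _pool(tracks: Sequence[BinnedTrack]) -> np.ndarray:
    return np.concatenate(
        [vec for t in tracks for vec in t.values.values()]
    ).astype(float)


def quantile_normalize(
    target_tracks: Sequence[BinnedTrack],
    reference_tracks: Sequence[BinnedTrack],
) -> list[BinnedTrack]:
    """Map target tracks onto the reference group's pooled distribution.

    Empirical CDFs use plotting position ``(rank - 0.5) / n`` with ties
    assigned their average rank; the reference quantile function
    interpolates linearly between order statistics (clamping beyond the
    extremes).  Rank order within the target pool is preserved, and a
    constant target maps to the reference median.
    """
    if not reference_tracks:
        raise ValueError("reference pool is empty")
    if not target_tracks:
        return []
    layout = target_tracks[0]
    for t in list(target_tracks) + list(reference_tracks):
        if not layout.same_layout(t):
            raise ValueError(
                f"track {t.sample_id!r} does not share the target bin layout"
            )

    ref = np.sort(_pool(reference_tracks))
    ref_pos = (np.arange(len(ref)) + 0.5) / len(ref)

    target = _pool(target_tracks)
    probs = (rankdata(target, method="average") - 0.5) / len(target)
    mapped = np.interp(probs, ref_pos, ref)

    out: list[BinnedTrack] = []
    offset = 0
    for t in target_tracks:
        new = t.copy()
        for chrom in new.values:
            n = len(new.values[chrom])
            new.values[chrom] = mapped[offset : offset + n].copy()
            offset += n
        new.normalized = True
        out.append(new)
    return out
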