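"""Sliding-window detection of differentially methylated regions (DMRs).

Two sample groups ("treated" = A, "control" = B) are compared window by
window along the genome.  For a window R of m bins the per-bin group
profiles are

    a_j = mean over treated samples of bin j,   j = 1..m
    b_j = mean over control samples of bin j,

after removing, per sample and bin, intensities above the ``max_reads``
cap (a guard against pile-up artifacts).  The window's group levels
A_R,A and A_R,B are the means of the surviving per-bin profiles.  The
two profiles are then compared with a paired t-test, a Wilcoxon
signed-rank test (both two-sided, pairing across the m bins), or the
Pearson correlation r of a against b — for correlation, a *low* r
signals a methylation difference, so significance means r below the
threshold.

A window is reported when its statistic falls below ``p_threshold``;
type 1 (hyper) when the treated mean exceeds control, type 2 (hypo)
otherwise.  Overlapping significant windows are reported individually,
not merged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .normalization import NormalizationParams
from .track_io import BinnedTrack

__all__ = [
    "GroupAssignment",
    "DMRParams",
    "DMRRecord",
    "region_profiles",
    "region_test",
    "dmr_scan",
]

TREATED = "treated"
CONTROL = "control"


@dataclass(frozen=True)
class GroupAssignment:
    """Partition of sample ids into treated (A) and control (B)."""

    labels: dict[str, str]

    def __post_init__(self) -> None:
        bad = {g for g in self.labels.values() if g not in (TREATED, CONTROL)}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if not self.treated or not self.control:
            raise ValueError("both groups must be non-empty")

    @property
    def treated(self) -> list[str]:
        return [s for s, g in self.labels.items() if g == TREATED]

    @property
    def control(self) -> list[str]:
        return [s for s, g in self.labels.items() if g == CONTROL]

    @classmethod
    def from_tsv(cls, path) -> "GroupAssignment":
        labels: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 columns")
                labels[fields[0]] = fields[1]
        return cls(labels)


@dataclass(frozen=True)
class DMRParams:
    """Scan parameters with the tool's standard defaults."""

    normalization: NormalizationParams = field(default_factory=NormalizationParams)
    max_reads: float = 100.0
    min_reads: float = 0.3
    p_threshold: float = 0.01
    stat_method: str = "ttest"
    region_step: int = 500
    region_length: int = 1000

    def __post_init__(self) -> None:
        if self.stat_method not in ("ttest", "wilcoxon", "pearson"):
            raise ValueError(f"unknown stat method {self.stat_method!r}")
        if self.region_step <= 0:
            raise ValueError("region_step must be positive")
        if self.region_length <= 0:
            raise ValueError("region_length must be positive")


@dataclass(frozen=True)
class DMRRecord:
    """One significant window.

    ``stat_value`` is a p-value for the t and Wilcoxon methods and the
    correlation coefficient r for the Pearson method.  ``meth_ratio``
    is the difference divided by the control group's mean region
    intensity.
    """

    chrom: str
    start: int
    end: int
    dmr_type: int  # 1 = hyper (treated > control), 2 = hypo
    stat_value: float
    meth_difference: float
    meth_ratio: float


def _stack(tracks: Sequence[BinnedTrack], chrom: str, b0: int, b1: int) -> np.ndarray:
    return np.stack([t.values[chrom][b0:b1] for t in tracks]).astype(float)


def region_profiles(
    tracks_A: Sequence[BinnedTrack],
    tracks_B: Sequence[BinnedTrack],
    chrom: str,
    start_bin: int,
    m: int,
    max_reads: float = 100.0,
):
    """Per-bin group means over a window of ``m`` bins.

    Values above ``max_reads`` are removed per sample and bin before
    averaging; a bin whose value is missing in every sample of either
    group is dropped from both profiles (pairwise deletion).  Returns
    ``(a, b, A_RA, A_RB)`` or ``None`` when no bin survives.
    """
    A = _stack(tracks_A, chrom, start_bin, start_bin + m)
    B = _stack(tracks_B, chrom, start_bin, start_bin + m)
    A = np.where(A > max_reads, np.nan, A)
    B = np.where(B > max_reads, np.nan, B)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bin columns
        a = np.nanmean(A, axis=0)
        b = np.nanmean(B, axis=0)
    keep = ~(np.isnan(a) | np.isnan(b))
    if not keep.any():
        return None
    a, b = a[keep], b[keep]
    return a, b, float(a.mean()), float(b.mean())


def region_test(a: np.ndarray, b: np.ndarray, stat_method: str) -> float | None:
    """Compare two paired per-bin profiles.

    Returns a two-sided p-value (t-test, Wilcoxon signed-rank) or the
    Pearson correlation coefficient; ``None`` marks an untestable
    region (fewer than 2 surviving bins, or zero variance under the
    Pearson method).

    Degenerate paired cases: identically zero differences give p = 1;
    constant non-zero differences give p = 0 (the shift is exact but a
    t statistic is undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("profiles must have equal length")
    if len(a) < 2:
        return None

    if stat_method == "pearson":
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            return None
        return float(stats.pearsonr(a, b).statistic)

    d = a - b
    if np.all(d == 0):
        return 1.0
    if np.ptp(d) == 0:
        warnings.warn("constant non-zero paired differences; p set to 0")
        return 0.0

    if stat_method == "ttest":
        return float(stats.ttest_rel(a, b).pvalue)

    if stat_method == "wilcoxon":
        nz = d[d != 0]
        if len(nz) < 2:
            return 1.0
        method = "exact" if len(nz) <= 25 else "approx"
        res = stats.wilcoxon(nz, correction=(method == "approx"), method=method)
        return float(res.pvalue)

    raise ValueError(f"unknown stat method {stat_method!r}")


def _is_significant(stat_value: float, params: DMRParams) -> bool:
    # For p-value methods small p means significant; for Pearson a low
    # (or negative) correlation between the group profiles does.
    return stat_value < params.p_threshold


def dmr_scan(
    tracks_A: Sequence[BinnedTrack],
    tracks_B: Sequence[BinnedTrack],
    params: DMRParams = DMRParams(),
) -> list[DMRRecord]:
    """Scan the genome for differentially methylated windows.

    Windows of ``region_length`` start at 0 and advance by
    ``region_step`` on every chromosome; a terminal window clipped to
    less than half the region length is skipped.  Windows where both
    group means fall below ``min_reads`` are not tested.
    """
    if not tracks_A or not tracks_B:
        raise ValueError("both groups need at least one track")
    layout = tracks_A[0]
    for t in list(tracks_A) + list(tracks_B):
        if not t.normalized:
            raise ValueError(f"track {t.sample_id!r} is not normalized")
        if not layout.same_layout(t):
            raise ValueError(f"track {t.sample_id!r} has a different bin layout")

    bin_size = layout.bin_size
    if params.region_length < bin_size or params.region_length % bin_size:
        raise ValueError("region_length must be a positive multiple of bin_size")

    records: list[DMRRecord] = []
    for chrom, chrom_len in layout.genome.chrom_sizes.items():
        n_bins = layout.genome.n_bins(chrom, bin_size)
        for start in range(0, chrom_len, params.region_step):
            end = min(start + params.region_length, chrom_len)
            if end - start < params.region_length / 2:
                continue
            b0 = start // bin_size
            b1 = min(-(-end // bin_size), n_bins)
            prof = region_profiles(
                tracks_A, tracks_B, chrom, b0, b1 - b0, params.max_reads
            )
            if prof is None:
                continue
            a, b, A_RA, A_RB = prof
            if max(A_RA, A_RB) < params.min_reads:
                continue
            stat = region_test(a, b, params.stat_method)
            if stat is None or not _is_significant(stat, params):
                continue
            diff = A_RA - A_RB
            if diff == 0:
                continue  # significant statistic but no direction: not a DMR
            if A_RB > 0:
                ratio = diff / A_RB
            else:
                ratio = float("inf") if diff > 0 else float("-inf")
            records.append(
                DMRRecord(
                    chrom=chrom,
                    start=start,
                    end=end,
                    dmr_type=1 if diff > 0 else 2,
                    stat_value=stat,
                    meth_difference=diff,
                    meth_ratio=ratio,
                )
            )
    records.sort(key=lambda r: (r.chrom, r.start))
    return records
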