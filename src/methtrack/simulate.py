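"""Synthetic methylation cohorts with known truth.

The generator emulates the count structure of methylation-capture
sequencing at desk scale: per-bin read counts are Poisson around a
background rate (default 2 reads per 100-bp bin, matching a typical
enrichment library where most bins carry little signal), and
differentially methylated regions are implanted by multiplying the
rate inside chosen intervals for one group.  An optional dispersion
parameter switches to negative-binomial counts for overdispersion
stress tests.  All randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dmr import CONTROL, TREATED
from .track_io import BinnedTrack, Genome
from .genes import GeneAnnotation

__all__ = ["Implant", "SimulationSpec", "simulate_cohort", "simulate_annotations"]


@dataclass(frozen=True)
class Implant:
    """A differential interval: the named group's rate is multiplied."""

    chrom: str
    start: int
    end: int
    group: str = TREATED
    multiplier: float = 8.0

    def __post_init__(self) -> None:
        if self.multiplier <= 0:
            raise ValueError("multiplier must be positive")
        if not 0 <= self.start < self.end:
            raise ValueError("invalid implant interval")


@dataclass(frozen=True)
class SimulationSpec:
    seed: int = 0
    n_samples: dict[str, int] = field(
        default_factory=lambda: {TREATED: 5, CONTROL: 5}
    )
    chrom_sizes: dict[str, int] = field(default_factory=lambda: {"chr1": 60_000})
    bin_size: int = 100
    background_rate: float = 2.0
    implants: tuple[Implant, ...] = ()
    dispersion: float | None = None  # NB size parameter; None = Poisson
    n_genes: int = 10
    cpg_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.background_rate <= 0:
            raise ValueError("background rate must be positive")
        for imp in self.implants:
            if imp.chrom not in self.chrom_sizes:
                raise ValueError(f"implant on unknown chromosome {imp.chrom!r}")
            if imp.end > self.chrom_sizes[imp.chrom]:
                raise ValueError("implant extends past chromosome end")

    @property
    def genome(self) -> Genome:
        return Genome("synthetic", dict(self.chrom_sizes))


def _draw_counts(rng: np.random.Generator, rate: np.ndarray, dispersion) -> np.ndarray:
    if dispersion is None:
        return rng.poisson(rate).astype(float)
    p = dispersion / (dispersion + rate)
    return rng.negative_binomial(dispersion, p).astype(float)


def simulate_cohort(
    spec: SimulationSpec,
) -> tuple[dict[str, list[BinnedTrack]], list[Implant]]:
    """Draw per-sample raw count tracks for every group.

    Returns ``(tracks_by_group, truth)`` where truth is the list of
    implanted intervals.  Tracks are raw counts (not normalized) with
    ``total_unique_reads`` set to the number of simulated reads.
    """
    rng = np.random.default_rng(spec.seed)
    genome = spec.genome
    tracks: dict[str, list[BinnedTrack]] = {}
    for group in sorted(spec.n_samples):
        n = spec.n_samples[group]
        if n < 1:
            raise ValueError(f"group {group!r} needs at least one sample")
        tracks[group] = []
        for i in range(n):
            track = BinnedTrack.zeros(f"{group}{i + 1}", genome, spec.bin_size)
            for chrom, vec in track.values.items():
                rate = np.full(len(vec), spec.background_rate)
                for imp in spec.implants:
                    if imp.group == group and imp.chrom == chrom:
                        b0 = imp.start // spec.bin_size
                        b1 = -(-imp.end // spec.bin_size)
                        rate[b0:b1] = spec.background_rate * imp.multiplier
                track.values[chrom] = _draw_counts(rng, rate, spec.dispersion)
            track.total_unique_reads = float(
                sum(v.sum() for v in track.values.values())
            )
            tracks[group].append(track)
    return tracks, list(spec.implants)


def simulate_annotations(
    spec: SimulationSpec,
) -> tuple[list[GeneAnnotation], list[tuple[str, int, int]]]:
    """Place non-overlapping genes and CpG islands on the genome.

    Transcription start sites sit at the centers of equal slots along
    each chromosome, so promoter windows (TSS +/- 2 kb) of distinct
    genes never share an island when slots are wide enough; strands are
    random.  Exactly ``round(cpg_fraction * n_genes)`` promoters get a
    200-bp CpG island centered on their TSS, making the flagged
    fraction exact by construction.
    """
    if spec.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    chroms = list(spec.chrom_sizes)
    # round-robin allocation of genes to chromosomes
    per_chrom = {c: 0 for c in chroms}
    for i in range(spec.n_genes):
        per_chrom[chroms[i % len(chroms)]] += 1

    genes: list[GeneAnnotation] = []
    gid = 0
    for chrom in chroms:
        n_here = per_chrom[chrom]
        if n_here == 0:
            continue
        length = spec.chrom_sizes[chrom]
        slot = length // n_here
        if slot < 4200:
            raise ValueError(
                f"{chrom}: {n_here} genes need >= 4.2 kb per gene to keep "
                "promoter windows island-disjoint"
            )
        body = min(2000, slot // 3)
        for j in range(n_here):
            gid += 1
            center = j * slot + slot // 2
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                tx_start, tx_end = center, min(center + body, length)
            else:
                tx_start, tx_end = max(0, center - body), center
            genes.append(
                GeneAnnotation(
                    symbol=f"GENE{gid}",
                    accession=f"TX{gid:04d}",
                    chrom=chrom,
                    strand=strand,
                    tx_start=tx_start,
                    tx_end=tx_end,
                )
            )

    n_flagged = round(spec.cpg_fraction * len(genes))
    flagged = rng.choice(len(genes), size=n_flagged, replace=False)
    islands: list[tuple[str, int, int]] = []
    for idx in sorted(flagged):
        g = genes[idx]
        start = max(0, g.tss - 100)
        end = min(spec.chrom_sizes[g.chrom], g.tss + 100)
        islands.append((g.chrom, start, end))
    return genes, islands
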