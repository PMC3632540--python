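"""Genomic interval and binned-track I/O.

Methylation-enrichment sequencing (MBDCap-seq / MeDIP-seq) is summarized
here as fixed-width per-bin read counts along each chromosome, by default
at 100-bp resolution.  A read contributes one count to every bin it
overlaps by at least one base pair, so a boundary-spanning read increments
two (or more) bins.

Coordinates are 0-based half-open (BED convention) everywhere, including
the DMR result table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

__all__ = [
    "Genome",
    "ReadInterval",
    "BinnedTrack",
    "TrackFormatError",
    "read_chrom_sizes",
    "read_bed",
    "bin_reads",
    "read_track",
    "write_track",
    "write_dmr_output",
    "read_dmr_output",
]


class TrackFormatError(ValueError):
    """Raised for malformed interval or track files."""


@dataclass(frozen=True)
class Genome:
    """A chromosome layout: names and lengths in base pairs."""

    assembly_label: str
    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        for name, length in self.chrom_sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)

    def n_bins(self, chrom: str, bin_size: int) -> int:
        """Number of bins on one chromosome; the last bin may be short."""
        return math.ceil(self.chrom_sizes[chrom] / bin_size)

    def total_bins(self, bin_size: int) -> int:
        """Total bin number across the genome (the N_bin of linear normalization)."""
        return sum(self.n_bins(c, bin_size) for c in self.chrom_sizes)


class ReadInterval(NamedTuple):
    """One mapped read as a 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int


@dataclass
class BinnedTrack:
    """Per-bin methylation intensity of one sample across a genome.

    ``values`` maps chromosome name to a float vector of length
    ``ceil(chrom_length / bin_size)``.  Raw tracks hold integer read
    counts; after normalization ``normalized`` is set and values are
    non-negative reals.  ``total_unique_reads`` is the library size used
    by linear normalization; it defaults to the number of binned reads
    but may be overridden when the library contains reads outside the
    analyzed chromosomes.
    """

    sample_id: str
    genome: Genome
    bin_size: int
    values: dict[str, np.ndarray]
    total_unique_reads: float = 0.0
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for chrom, vec in self.values.items():
            expected = self.genome.n_bins(chrom, self.bin_size)
            if len(vec) != expected:
                raise ValueError(
                    f"{chrom}: expected {expected} bins, got {len(vec)}"
                )

    @classmethod
    def zeros(cls, sample_id: str, genome: Genome, bin_size: int = 100) -> "BinnedTrack":
        values = {
            c: np.zeros(genome.n_bins(c, bin_size)) for c in genome.chrom_sizes
        }
        return cls(sample_id, genome, bin_size, values)

    def copy(self) -> "BinnedTrack":
        return BinnedTrack(
            sample_id=self.sample_id,
            genome=self.genome,
            bin_size=self.bin_size,
            values={c: v.copy() for c, v in self.values.items()},
            total_unique_reads=self.total_unique_reads,
            normalized=self.normalized,
        )

    def same_layout(self, other: "BinnedTrack") -> bool:
        return (
            self.bin_size == other.bin_size
            and self.genome.chrom_sizes == other.genome.chrom_sizes
        )


def read_chrom_sizes(path, assembly_label: str = "custom") -> Genome:
    """Read a two-column ``<chrom>\\t<length>`` TSV into a :class:`Genome`."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise TrackFormatError(f"{path}:{lineno}: expected 2 columns")
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError as exc:
                raise TrackFormatError(f"{path}:{lineno}: bad length {fields[1]!r}") from exc
            if name in sizes:
                raise TrackFormatError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            sizes[name] = length
    return Genome(assembly_label, sizes)


def read_bed(path, genome: Genome | None = None) -> tuple[list[ReadInterval], int]:
    """Read BED3+ intervals.

    Returns the intervals in file order and the number of lines skipped
    because their chromosome is absent from ``genome`` (0 when no genome
    is given).  Malformed lines raise :class:`TrackFormatError` naming
    the line number.
    """
    intervals: list[ReadInterval] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise TrackFormatError(f"{path}:{lineno}: expected >=3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise TrackFormatError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start < 0 or start >= end:
                raise TrackFormatError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            if genome is not None and chrom not in genome.chrom_sizes:
                skipped += 1
                continue
            intervals.append(ReadInterval(chrom, start, end))
    return intervals, skipped


def bin_reads(
    reads: Iterable[ReadInterval],
    genome: Genome,
    bin_size: int = 100,
) -> BinnedTrack:
    """Accumulate reads into fixed-width bins.

    Bin ``b`` on a chromosome covers ``[b*bin_size, (b+1)*bin_size)``; a
    read adds 1 to every bin it overlaps by at least one base pair.
    Reads on chromosomes absent from the genome are skipped (their count
    is not added to ``total_unique_reads``).
    """
    track = BinnedTrack.zeros("binned", genome, bin_size)
    n_used = 0
    for read in reads:
        vec = track.values.get(read.chrom)
        if vec is None:
            continue
        first = read.start // bin_size
        last = (read.end - 1) // bin_size
        last = min(last, len(vec) - 1)
        if first >= len(vec):
            continue
        vec[first : last + 1] += 1
        n_used += 1
    track.total_unique_reads = float(n_used)
    return track


def write_track(track: BinnedTrack, path) -> None:
    """Write a fixed-bin bedGraph file; zero bins are omitted.

    Metadata needed for a lossless round trip (sample id, bin size,
    library size, normalization flag, chromosome layout) goes into
    comment headers.
    """
    with open(path, "w") as fh:
        fh.write(f"# sample_id={track.sample_id}\n")
        fh.write(f"# bin_size={track.bin_size}\n")
        fh.write(f"# total_unique_reads={track.total_unique_reads!r}\n")
        fh.write(f"# normalized={int(track.normalized)}\n")
        for chrom, length in track.genome.chrom_sizes.items():
            fh.write(f"# chrom={chrom}\tlength={length}\n")
        fh.write(f'track type=bedGraph name="{track.sample_id}"\n')
        for chrom, vec in track.values.items():
            length = track.genome.chrom_sizes[chrom]
            nz = np.nonzero(vec)[0]
            for b in nz:
                start = int(b) * track.bin_size
                end = min(start + track.bin_size, length)
                fh.write(f"{chrom}\t{start}\t{end}\t{float(vec[b])!r}\n")


def read_track(path) -> BinnedTrack:
    """Read a track written by :func:`write_track`.

    Interval widths must equal the bin size (the final bin may be
    shorter) and starts must be bin-aligned; anything else raises
    :class:`TrackFormatError`.
    """
    meta: dict[str, str] = {}
    sizes: dict[str, int] = {}
    rows: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("# chrom="):
                parts = dict(p.split("=", 1) for p in line[2:].split("\t"))
                sizes[parts["chrom"]] = int(parts["length"])
                continue
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key] = value
                continue
            if line.startswith(("track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise TrackFormatError(f"{path}:{lineno}: expected 4 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise TrackFormatError(f"{path}:{lineno}: bad numeric field") from exc
            rows.append((fields[0], start, end, value))

    if "bin_size" not in meta or not sizes:
        raise TrackFormatError(f"{path}: missing bin_size/chromosome headers")
    bin_size = int(meta["bin_size"])
    genome = Genome(meta.get("assembly", "custom"), sizes)
    track = BinnedTrack.zeros(meta.get("sample_id", "track"), genome, bin_size)
    track.total_unique_reads = float(meta.get("total_unique_reads", 0.0))
    track.normalized = bool(int(meta.get("normalized", "0")))
    for chrom, start, end, value in rows:
        if chrom not in sizes:
            raise TrackFormatError(f"{path}: interval on unknown chromosome {chrom!r}")
        if start % bin_size != 0:
            raise TrackFormatError(
                f"{path}: interval start {start} not aligned to {bin_size}-bp bins"
            )
        b = start // bin_size
        expected_end = min(start + bin_size, sizes[chrom])
        if end != expected_end:
            raise TrackFormatError(
                f"{path}: interval [{start},{end}) has width != bin size {bin_size}"
            )
        track.values[chrom][b] = value
    return track


def _format_sig(x: float, scientific: bool) -> str:
    if scientific:
        return f"{x:.3e}"
    return f"{x:.4g}"


def write_dmr_output(records, path) -> None:
    """Write DMR records as a 7-column TSV.

    Columns: chromosome, region start, region end (0-based half-open),
    DMR type (1 = hyper, treated above control; 2 = hypo), statistic
    value (p-value, or correlation coefficient under the Pearson
    method), signed methylation difference, methylation ratio
    (difference divided by the control group's mean intensity).  A
    positive difference must carry type 1 and a negative one type 2.
    """
    lines = []
    for rec in records:
        if rec.dmr_type not in (1, 2):
            raise ValueError(f"invalid DMR type {rec.dmr_type!r}")
        if rec.dmr_type == 1 and not rec.meth_difference > 0:
            raise ValueError(
                f"type-1 (hyper) record at {rec.chrom}:{rec.start} has "
                f"non-positive difference {rec.meth_difference}"
            )
        if rec.dmr_type == 2 and rec.meth_difference > 0:
            raise ValueError(
                f"type-2 (hypo) record at {rec.chrom}:{rec.start} has "
                f"positive difference {rec.meth_difference}"
            )
        lines.append(
            "\t".join(
                (
                    rec.chrom,
                    str(rec.start),
                    str(rec.end),
                    str(rec.dmr_type),
                    _format_sig(rec.stat_value, scientific=True),
                    _format_sig(rec.meth_difference, scientific=False),
                    _format_sig(rec.meth_ratio, scientific=False),
                )
            )
        )
    with open(path, "w") as fh:
        for line in lines:
            fh.write(line + "\n")


def read_dmr_output(path) -> list:
    """Parse a DMR TSV back into records (inverse of :func:`write_dmr_output`)."""
    from .dmr import DMRRecord  # local import to avoid a cycle

    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise TrackFormatError(f"{path}:{lineno}: expected 7 columns")
            records.append(
                DMRRecord(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    dmr_type=int(fields[3]),
                    stat_value=float(fields[4]),
                    meth_difference=float(fields[5]),
                    meth_ratio=float(fields[6]),
                )
            )
    return records
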