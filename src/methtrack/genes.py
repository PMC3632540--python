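"""Promoter-level methylation: TSS windows, promoter matrix, correlated genes.

Promoter methylation of a gene is the mean normalized intensity over
the bins overlapping TSS +/- 2 kb, where the TSS is the transcription
start (txStart) for plus-strand genes and the transcription end
(txEnd) for minus-strand genes.  Each transcript (accession) is a row
of the promoter matrix; columns are samples.  Promoters are flagged
when a CpG island overlaps the window by at least one base pair.

The correlated-gene search ranks, for a query transcript, the other
rows of the matrix by Pearson correlation of their promoter profiles
across samples, keeping positive correlations above a floor (default
0.4) and at most the top ``k`` (default 40).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .track_io import BinnedTrack, Genome, TrackFormatError

__all__ = [
    "GeneAnnotation",
    "PromoterMatrix",
    "read_annotations",
    "read_cpg_islands",
    "read_gene_sets",
    "tss_window",
    "promoter_matrix",
    "cpg_island_flag",
    "correlated_genes",
    "null_correlation_tail",
]


@dataclass(frozen=True)
class GeneAnnotation:
    symbol: str
    accession: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.accession}: strand must be + or -")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"{self.accession}: txStart must be < txEnd")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end


@dataclass
class PromoterMatrix:
    """Transcript x sample promoter methylation with CpG-island flags.

    ``values`` is a DataFrame indexed by accession; ``symbols`` maps
    accession -> gene symbol; ``cpg_flag`` is a boolean Series on the
    same index.  Missing entries (windows with no covered bins) are NaN.
    """

    values: pd.DataFrame
    symbols: pd.Series
    cpg_flag: pd.Series

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "symbol", self.symbols)
        out.insert(1, "cpg_island", self.cpg_flag.astype(int))
        out.to_csv(path, sep="\t", index_label="accession")


def read_annotations(path) -> list[GeneAnnotation]:
    """Read gene annotations from BED6 or a refGene-like TSV.

    BED6 columns: chrom, start, end, name (symbol|accession or symbol),
    score, strand.  refGene-like columns: symbol, accession, chrom,
    strand, txStart, txEnd.
    """
    genes: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if len(fields) >= 6 and fields[5] in ("+", "-"):
                    name = fields[3]
                    symbol, _, accession = name.partition("|")
                    genes.append(
                        GeneAnnotation(
                            symbol=symbol,
                            accession=accession or symbol,
                            chrom=fields[0],
                            strand=fields[5],
                            tx_start=int(fields[1]),
                            tx_end=int(fields[2]),
                        )
                    )
                elif len(fields) >= 6:
                    genes.append(
                        GeneAnnotation(
                            symbol=fields[0],
                            accession=fields[1],
                            chrom=fields[2],
                            strand=fields[3],
                            tx_start=int(fields[4]),
                            tx_end=int(fields[5]),
                        )
                    )
                else:
                    raise ValueError("expected >=6 columns")
            except ValueError as exc:
                raise TrackFormatError(f"{path}:{lineno}: {exc}") from exc
    return genes


def read_cpg_islands(path) -> list[tuple[str, int, int]]:
    """Read CpG islands from BED3 as (chrom, start, end) tuples."""
    from .track_io import read_bed

    intervals, _ = read_bed(path)
    return [(i.chrom, i.start, i.end) for i in intervals]


def read_gene_sets(path) -> dict[str, list[str]]:
    """Parse a GMT file (set name, description, member symbols).

    Symbols are uppercased; sets keep their file order.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise TrackFormatError(
                    f"{path}:{lineno}: GMT lines need name, description and >=1 gene"
                )
            sets[fields[0]] = [g.upper() for g in fields[2:] if g]
    return sets


def tss_window(
    gene: GeneAnnotation, genome: Genome | None = None, flank: int = 2000
) -> tuple[int, int]:
    """Half-open promoter interval [TSS - flank, TSS + flank), clipped."""
    if flank <= 0:
        raise ValueError("flank must be positive")
    start = max(0, gene.tss - flank)
    end = gene.tss + flank
    if genome is not None and gene.chrom in genome.chrom_sizes:
        end = min(end, genome.chrom_sizes[gene.chrom])
    return start, end


def cpg_island_flag(
    gene: GeneAnnotation,
    cpg_islands: Sequence[tuple[str, int, int]],
    genome: Genome | None = None,
    flank: int = 2000,
) -> bool:
    """True iff any island overlaps the promoter window by >= 1 bp."""
    w_start, w_end = tss_window(gene, genome, flank)
    return any(
        chrom == gene.chrom and start < w_end and end > w_start
        for chrom, start, end in cpg_islands
    )


def promoter_matrix(
    tracks: Sequence[BinnedTrack],
    annotations: Sequence[GeneAnnotation],
    cpg_islands: Sequence[tuple[str, int, int]] = (),
    flank: int = 2000,
    collapse: bool = False,
) -> PromoterMatrix:
    """Mean promoter intensity for every transcript and sample.

    Bins partially overlapping the window are included whole (the
    window is snapped outward to bin boundaries).  Transcripts on
    chromosomes absent from the tracks are skipped.  With ``collapse``
    only the longest transcript per symbol is kept.
    """
    if not tracks:
        raise ValueError("need at least one track")
    layout = tracks[0]
    for t in tracks[1:]:
        if not layout.same_layout(t):
            raise ValueError(f"track {t.sample_id!r} has a different bin layout")
    if not all(t.normalized for t in tracks):
        raise ValueError("promoter matrix requires normalized tracks")

    if collapse:
        best: dict[str, GeneAnnotation] = {}
        for g in annotations:
            cur = best.get(g.symbol)
            if cur is None or (g.tx_end - g.tx_start) > (cur.tx_end - cur.tx_start):
                best[g.symbol] = g
        annotations = [best[s] for s in sorted(best)]

    bin_size = layout.bin_size
    rows, accs, syms, flags = [], [], [], []
    for gene in annotations:
        if gene.chrom not in layout.values:
            continue
        w_start, w_end = tss_window(gene, layout.genome, flank)
        b0 = w_start // bin_size
        b1 = min(-(-w_end // bin_size), len(layout.values[gene.chrom]))
        if b1 <= b0:
            row = [math.nan] * len(tracks)
        else:
            row = [float(t.values[gene.chrom][b0:b1].mean()) for t in tracks]
        rows.append(row)
        accs.append(gene.accession)
        syms.append(gene.symbol)
        flags.append(cpg_island_flag(gene, cpg_islands, layout.genome, flank))

    values = pd.DataFrame(
        rows, index=pd.Index(accs, name="accession"), columns=[t.sample_id for t in tracks]
    )
    return PromoterMatrix(
        values=values,
        symbols=pd.Series(syms, index=values.index, name="symbol"),
        cpg_flag=pd.Series(flags, index=values.index, name="cpg_island"),
    )


def correlated_genes(
    matrix: PromoterMatrix,
    query: str,
    k: int = 40,
    min_rho: float = 0.4,
) -> list[tuple[str, float]]:
    """Top-``k`` transcripts whose promoter profile correlates with the query.

    ``query`` may be an accession or a gene symbol (first matching
    transcript).  Pearson correlation is computed pairwise-complete
    over samples with values in both rows; only rho >= ``min_rho``
    qualifies (anticorrelated genes never appear).  Ties are broken by
    accession for a deterministic ranking.
    """
    values = matrix.values
    if query in values.index:
        acc = query
    else:
        hits = matrix.symbols[matrix.symbols == query]
        if hits.empty:
            raise KeyError(f"query {query!r} not in matrix")
        acc = hits.index[0]
    qrow = values.loc[acc]
    if qrow.dropna().nunique() <= 1:
        raise ValueError(f"query {acc!r} has a constant promoter profile")

    others = values.drop(index=acc)
    rho = others.apply(lambda row: row.corr(qrow, min_periods=3), axis=1)
    rho = rho.dropna()
    rho = rho[rho >= min_rho]
    ranked = sorted(rho.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(a, float(r)) for a, r in ranked[:k]]


def null_correlation_tail(rho: float, n: int) -> float:
    """Two-sided tail P(|r| >= rho) for independent normal samples.

    Uses the exact relation t = r * sqrt(n-2) / sqrt(1-r^2) with a
    Student-t distribution on n-2 degrees of freedom.
    """
    if not 0 <= abs(rho) < 1:
        raise ValueError("rho must satisfy |rho| < 1")
    if n < 3:
        raise ValueError("need at least 3 samples")
    if rho == 0:
        return 1.0
    t = abs(rho) * math.sqrt(n - 2) / math.sqrt(1 - rho * rho)
    return float(2 * stats.t.sf(t, n - 2))
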