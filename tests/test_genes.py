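import math

import numpy as np
import pytest

from methtrack import (
    GeneAnnotation,
    correlated_genes,
    cpg_island_flag,
    null_correlation_tail,
    promoter_matrix,
    read_annotations,
    read_gene_sets,
    tss_window,
)
from methtrack.genes import PromoterMatrix
from methtrack.track_io import BinnedTrack, Genome, TrackFormatError

import pandas as pd


def _track(values, sample_id, genome, bin_size=100):
    return BinnedTrack(
        sample_id, genome, bin_size, {"chr1": np.asarray(values, float)},
        normalized=True,
    )


GENOME = Genome("toy", {"chr1": 60_000})


class TestTssWindow:
    def test_plus_strand_uses_tx_start(self):
        g = GeneAnnotation("A", "TX1", "chr1", "+", 10000, 12000)
        assert tss_window(g) == (8000, 12000)

    def test_minus_strand_uses_tx_end(self):
        g = GeneAnnotation("B", "TX2", "chr1", "-", 46000, 50000)
        assert tss_window(g) == (48000, 52000)

    def test_clipped_at_chromosome_bounds(self):
        g = GeneAnnotation("C", "TX3", "chr1", "+", 500, 5000)
        assert tss_window(g) == (0, 2500)
        g2 = GeneAnnotation("D", "TX4", "chr1", "-", 55000, 59500)
        assert tss_window(g2, GENOME) == (57500, 60000)


class TestCpGFlag:
    GENE = GeneAnnotation("A", "TX1", "chr1", "+", 10000, 12000)  # window [8000,12000)

    def test_overlapping_island(self):
        assert cpg_island_flag(self.GENE, [("chr1", 9000, 9500)])

    def test_adjacent_island_excluded_half_open(self):
        assert not cpg_island_flag(self.GENE, [("chr1", 12000, 12500)])

    def test_single_bp_overlap_counts(self):
        assert cpg_island_flag(self.GENE, [("chr1", 7500, 8001)])

    def test_empty_island_set(self):
        assert not cpg_island_flag(self.GENE, [])

    def test_other_chromosome_ignored(self):
        assert not cpg_island_flag(self.GENE, [("chr2", 9000, 9500)])


class TestPromoterMatrix:
    def test_constant_track_identity(self):
        tracks = [_track([4.0] * 600, "s1", GENOME)]
        genes = [GeneAnnotation("A", "TX1", "chr1", "+", 10000, 12000)]
        matrix = promoter_matrix(tracks, genes)
        assert matrix.values.loc["TX1", "s1"] == pytest.approx(4.0)

    def test_window_mean_over_bins(self):
        # gene window snapped to bins [1,2,3,4] holding [0,2,4,6] -> 3.0
        values = np.zeros(600)
        values[1:5] = [0, 2, 4, 6]
        genes = [GeneAnnotation("A", "TX1", "chr1", "+", 300, 5000)]
        matrix = promoter_matrix([_track(values, "s1", GENOME)], genes, flank=200)
        # window [100, 500) covers bins 1..4
        assert matrix.values.loc["TX1", "s1"] == pytest.approx(3.0)

    def test_shared_tss_gives_identical_rows(self):
        rng = np.random.default_rng(0)
        tracks = [_track(rng.poisson(3, 600), "s1", GENOME)]
        genes = [
            GeneAnnotation("A", "TX1", "chr1", "+", 10000, 12000),
            GeneAnnotation("A", "TX2", "chr1", "+", 10000, 15000),
        ]
        matrix = promoter_matrix(tracks, genes)
        assert matrix.values.loc["TX1", "s1"] == matrix.values.loc["TX2", "s1"]

    def test_outside_window_data_irrelevant(self):
        base = np.zeros(600)
        base[80:120] = 5.0
        other = base.copy()
        other[300:400] = 99.0  # far from the window
        genes = [GeneAnnotation("A", "TX1", "chr1", "+", 10000, 12000)]
        m1 = promoter_matrix([_track(base, "s1", GENOME)], genes)
        m2 = promoter_matrix([_track(other, "s1", GENOME)], genes)
        assert m1.values.loc["TX1", "s1"] == m2.values.loc["TX1", "s1"]

    def test_unknown_chromosome_skipped(self):
        genes = [
            GeneAnnotation("A", "TX1", "chr1", "+", 10000, 12000),
            GeneAnnotation("B", "TX2", "chr9", "+", 10000, 12000),
        ]
        matrix = promoter_matrix([_track(np.ones(600), "s1", GENOME)], genes)
        assert matrix.genes == ["TX1"]

    def test_collapse_keeps_longest_transcript(self):
        genes = [
            GeneAnnotation("A", "TX1", "chr1", "+", 10000, 12000),
            GeneAnnotation("A", "TX2", "chr1", "+", 10000, 20000),
        ]
        matrix = promoter_matrix(
            [_track(np.ones(600), "s1", GENOME)], genes, collapse=True
        )
        assert matrix.genes == ["TX2"]

    def test_raw_tracks_rejected(self):
        track = _track(np.ones(600), "s1", GENOME)
        track.normalized = False
        with pytest.raises(ValueError, match="normalized"):
            promoter_matrix([track], [])


def _matrix_from(values: np.ndarray, accs=None) -> PromoterMatrix:
    accs = accs or [f"TX{i:03d}" for i in range(len(values))]
    df = pd.DataFrame(values, index=pd.Index(accs, name="accession"),
                      columns=[f"s{j}" for j in range(values.shape[1])])
    return PromoterMatrix(
        values=df,
        symbols=pd.Series([a.replace("TX", "G") for a in accs], index=df.index),
        cpg_flag=pd.Series(False, index=df.index),
    )


class TestCorrelatedGenes:
    def test_duplicated_row_ranks_first(self):
        rng = np.random.default_rng(1)
        values = rng.lognormal(0, 1, (10, 8))
        values[3] = values[0]
        matrix = _matrix_from(values)
        ranked = correlated_genes(matrix, "TX000")
        assert ranked[0][0] == "TX003"
        assert ranked[0][1] == pytest.approx(1.0)

    def test_anticorrelated_rows_excluded(self):
        rng = np.random.default_rng(2)
        values = rng.lognormal(0, 1, (5, 8))
        values[1] = 2 * values[0].mean() - values[0]  # rho = -1 with the query
        ranked = correlated_genes(_matrix_from(values), "TX000")
        assert all(acc != "TX001" for acc, _ in ranked)

    def test_truncates_to_k_and_respects_floor(self):
        rng = np.random.default_rng(3)
        query = rng.normal(10, 2, 12)
        rows = [query]
        for i in range(30):
            rows.append(query + rng.normal(0, 0.5 + 0.2 * i, 12))
        values = np.abs(np.array(rows))
        ranked = correlated_genes(_matrix_from(values), "TX000", k=5, min_rho=0.4)
        assert len(ranked) <= 5
        assert all(r >= 0.4 for _, r in ranked)
        assert [r for _, r in ranked] == sorted((r for _, r in ranked), reverse=True)

    def test_matches_bruteforce_all_pairs(self):
        rng = np.random.default_rng(4)
        shared = rng.normal(0, 1, 15)
        values = np.abs(
            shared[None, :] * rng.uniform(0.5, 2, (60, 1))
            + rng.normal(0, 1.0, (60, 15))
        )
        matrix = _matrix_from(values)
        ranked = correlated_genes(matrix, "TX000", k=40, min_rho=0.4)
        # brute force from covariance sums
        q = values[0]
        expected = []
        for i in range(1, 60):
            x = values[i]
            cx, cq = x - x.mean(), q - q.mean()
            rho = float(np.sum(cx * cq) / math.sqrt(np.sum(cx**2) * np.sum(cq**2)))
            if rho >= 0.4:
                expected.append((f"TX{i:03d}", rho))
        expected.sort(key=lambda kv: (-kv[1], kv[0]))
        assert [a for a, _ in ranked] == [a for a, _ in expected[:40]]
        for (_, got), (_, want) in zip(ranked, expected):
            assert got == pytest.approx(want, abs=1e-12)

    def test_constant_query_rejected(self):
        values = np.ones((4, 6))
        with pytest.raises(ValueError, match="constant"):
            correlated_genes(_matrix_from(values), "TX000")

    def test_query_by_symbol(self):
        rng = np.random.default_rng(5)
        values = rng.lognormal(0, 1, (6, 8))
        ranked_sym = correlated_genes(_matrix_from(values), "G000", min_rho=-1.0)
        ranked_acc = correlated_genes(_matrix_from(values), "TX000", min_rho=-1.0)
        assert ranked_sym == ranked_acc


class TestNullCorrelationTail:
    def test_classical_critical_value(self):
        assert null_correlation_tail(0.632, 10) == pytest.approx(0.05, abs=0.001)

    def test_zero_correlation(self):
        assert null_correlation_tail(0.0, 25) == 1.0

    def test_monotone_in_rho_and_n(self):
        rhos = [0.1, 0.2, 0.4, 0.6, 0.8]
        tails = [null_correlation_tail(r, 30) for r in rhos]
        assert tails == sorted(tails, reverse=True)
        ns = [5, 10, 50, 200]
        tails_n = [null_correlation_tail(0.3, n) for n in ns]
        assert tails_n == sorted(tails_n, reverse=True)

    def test_matches_monte_carlo(self):
        rng = np.random.default_rng(6)
        n, reps, rho = 30, 100_000, 0.3
        x = rng.normal(size=(reps, n))
        y = rng.normal(size=(reps, n))
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        r = (xc * yc).sum(axis=1) / np.sqrt(
            (xc**2).sum(axis=1) * (yc**2).sum(axis=1)
        )
        mc = np.mean(np.abs(r) >= rho)
        se = math.sqrt(mc * (1 - mc) / reps)
        assert abs(null_correlation_tail(rho, n) - mc) < 3 * se

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            null_correlation_tail(1.0, 30)
        with pytest.raises(ValueError):
            null_correlation_tail(0.4, 2)


class TestFileFormats:
    def test_refgene_like_annotations(self, tmp_path):
        path = tmp_path / "genes.tsv"
        path.write_text("HOXB2\tNM_002145\tchr17\t-\t46620017\t46622393\n")
        (gene,) = read_annotations(path)
        assert gene.symbol == "HOXB2" and gene.strand == "-"
        assert gene.tss == gene.tx_end

    def test_bed6_annotations(self, tmp_path):
        path = tmp_path / "genes.bed"
        path.write_text("chr1\t1000\t5000\tGENEA|TX1\t0\t+\n")
        (gene,) = read_annotations(path)
        assert (gene.symbol, gene.accession, gene.tss) == ("GENEA", "TX1", 1000)

    def test_gmt_parsing(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("SETA\tdesc\thoxb2\tHOXB4\n")
        assert read_gene_sets(path) == {"SETA": ["HOXB2", "HOXB4"]}

    def test_gmt_short_line_rejected(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("SETA\tdesc\n")
        with pytest.raises(TrackFormatError, match=":1"):
            read_gene_sets(path)

    def test_empty_gmt(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("")
        assert read_gene_sets(path) == {}
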