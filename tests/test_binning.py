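"""Bin layouts, track summarization, and summary-bin selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromtx.annotation import TranscriptRecord
from chromtx.binning import (
    BinnedFeatureMatrix,
    BinSpec,
    apply_bin_spec,
    build_bin_layout,
    read_track,
    select_bin_spec,
    summarize_track,
)

PLUS = TranscriptRecord("t+", "g+", "chr1", 10000, 20000, "+")
MINUS = TranscriptRecord("t-", "g-", "chr1", 10000, 20000, "-")


class TestLayoutGeometry:
    def test_plus_strand_bins(self):
        lay = build_bin_layout(PLUS, "tx81")
        assert lay.n_bins == 81
        assert tuple(lay.bins[0]) == (8000, 8100)       # TSS - 2kb
        assert tuple(lay.bins[40]) == (12000, 18000)    # body
        assert tuple(lay.bins[80]) == (21900, 22000)    # TTS + 2kb

    def test_minus_strand_mirrored(self):
        lay = build_bin_layout(MINUS, "tx81")
        # tss = 20000; most-5' bin sits at [21900, 22000) in genome coordinates
        assert tuple(lay.bins[0]) == (21900, 22000)
        assert tuple(lay.bins[40]) == (12000, 18000)
        assert tuple(lay.bins[80]) == (8000, 8100)

    def test_tss41_mode(self):
        lay = build_bin_layout(PLUS, "tss41")
        assert lay.n_bins == 41
        assert tuple(lay.bins[40]) == (12000, 18000)

    def test_minimal_length_body_width(self):
        tx = TranscriptRecord("t", "g", "chr1", 10000, 14101, "+")
        lay = build_bin_layout(tx, "tx81")
        body = lay.bins[40]
        assert body[1] - body[0] == 101

    def test_too_short_transcript_errors(self):
        tx = TranscriptRecord("t", "g", "chr1", 10000, 14100, "+")
        with pytest.raises(ValueError, match="4100"):
            build_bin_layout(tx, "tx81")

    @pytest.mark.parametrize("tx", [PLUS, MINUS], ids=["plus", "minus"])
    def test_bins_tile_extended_gene_without_gaps(self, tx):
        lay = build_bin_layout(tx, "tx81")
        widths = lay.bins[:, 1] - lay.bins[:, 0]
        assert (widths[:40] == 100).all() and (widths[41:] == 100).all()
        # 5'->3' adjacency: each bin's 3' edge is the next bin's 5' edge
        if tx.strand == "+":
            assert (lay.bins[:-1, 1] == lay.bins[1:, 0]).all()
        else:
            assert (lay.bins[:-1, 0] == lay.bins[1:, 1]).all()
        covered = int(widths.sum())
        assert covered == tx.length + 2 * 2000


class TestSummarizeTrack:
    def write(self, tmp_path, lines):
        p = tmp_path / "t.bedGraph"
        p.write_text("".join(lines))
        return read_track(p)

    def test_constant_track(self, tmp_path):
        track = self.write(tmp_path, ["chr1\t0\t30000\t7\n"])
        means = summarize_track(track, build_bin_layout(PLUS, "tx81"))
        assert np.allclose(means, 7.0)

    def test_uncovered_bases_count_as_zero(self, tmp_path):
        # first bin [8000, 8100): covered half at value 4 -> mean0 = 2
        track = self.write(tmp_path, ["chr1\t8000\t8050\t4\n"])
        means = summarize_track(track, build_bin_layout(PLUS, "tx81"))
        assert means[0] == pytest.approx(2.0)
        assert means[1] == 0.0

    def test_step_track_base_weighted_mean(self, tmp_path):
        # step 0 -> 10 at the midpoint of bin 0
        track = self.write(
            tmp_path, ["chr1\t7000\t8050\t0\n", "chr1\t8050\t9000\t10\n"]
        )
        means = summarize_track(track, build_bin_layout(PLUS, "tx81"))
        assert means[0] == pytest.approx(5.0)

    def test_missing_chromosome_errors(self, tmp_path):
        track = self.write(tmp_path, ["chr2\t0\t100\t1\n"])
        with pytest.raises(KeyError, match="chr1"):
            summarize_track(track, build_bin_layout(PLUS, "tx81"))

    def test_strand_mirrored_summary(self, tmp_path):
        """Mirroring both track and layout leaves the 5'->3' summary unchanged."""
        rng = np.random.default_rng(3)
        vals = rng.integers(0, 20, size=28)
        fwd = ["chr1\t%d\t%d\t%d\n" % (7000 + 500 * i, 7500 + 500 * i, v)
               for i, v in enumerate(vals)]
        # mirror around the midpoint of [10000, 20000): position x -> 30000 - x
        rev = ["chr1\t%d\t%d\t%d\n" % (30000 - (7500 + 500 * i), 30000 - (7000 + 500 * i), v)
               for i, v in enumerate(vals)]
        m_fwd = summarize_track(self.write(tmp_path, fwd), build_bin_layout(PLUS, "tx81"))
        m_rev = summarize_track(self.write(tmp_path, rev), build_bin_layout(MINUS, "tx81"))
        assert np.allclose(m_fwd, m_rev)


def random_matrix(rng, n_genes=200, n_bins=81):
    return pd.DataFrame(
        rng.lognormal(1.0, 1.0, size=(n_genes, n_bins)),
        index=[f"g{i}" for i in range(n_genes)],
    )


class TestSelectBinSpec:
    def test_planted_bin_found(self):
        rng = np.random.default_rng(0)
        df = random_matrix(rng)
        y = np.log2(df[17].to_numpy()) + rng.normal(0, 0.3, len(df))
        spec = select_bin_spec(BinnedFeatureMatrix("f", df), y, "bestbin")
        assert spec.selected_bins == [17]
        assert spec.selection_correlation > 0.8

    def test_negative_correlation_winner(self):
        rng = np.random.default_rng(1)
        df = random_matrix(rng)
        y = -np.log2(df[5].to_numpy()) + rng.normal(0, 0.3, len(df))
        spec = select_bin_spec(df, y, "bestbin")
        assert spec.selected_bins == [5]
        assert spec.selection_correlation < -0.8

    def test_tssbin_ignores_correlation(self):
        rng = np.random.default_rng(2)
        df = random_matrix(rng)
        y = np.log2(df[60].to_numpy())
        spec = select_bin_spec(df, y, "tssbin")
        assert spec.selected_bins == list(range(40))

    def test_allbins(self):
        rng = np.random.default_rng(2)
        df = random_matrix(rng)
        spec = select_bin_spec(df, rng.normal(size=len(df)), "allbins")
        assert spec.selected_bins == list(range(81))

    def test_zero_variance_bin_treated_as_zero_correlation(self):
        rng = np.random.default_rng(3)
        df = random_matrix(rng)
        df[12] = 5.0  # constant bin
        y = np.log2(df[30].to_numpy())
        spec = select_bin_spec(df, y, "bestbin")
        assert spec.selected_bins == [30]

    def test_best5bins_contains_planted(self):
        rng = np.random.default_rng(4)
        df = random_matrix(rng)
        y = np.log2(df[22].to_numpy()) + rng.normal(0, 0.2, len(df))
        spec = select_bin_spec(df, y, "best5bins")
        assert len(spec.selected_bins) == 5 and 22 in spec.selected_bins

    def test_matches_exhaustive_scan_oracle(self):
        """bestbin equals an independent exhaustive |r| scan, 20 seeds."""
        from chromtx.binning import _selection_log

        for seed in range(20):
            rng = np.random.default_rng(seed)
            df = random_matrix(rng, n_genes=120)
            k = int(rng.integers(0, 81))
            sign = -1 if seed % 2 else 1
            y = sign * np.log2(df[k].to_numpy()) + rng.normal(0, 0.5, len(df))
            spec = select_bin_spec(df, y, "bestbin")
            X = _selection_log(df.to_numpy())
            oracle = max(
                range(81), key=lambda j: abs(stats.pearsonr(X[:, j], y)[0])
            )
            assert spec.selected_bins == [oracle]


class TestApplyBinSpec:
    df = pd.DataFrame([[1.0, 2.0, 9.0, 4.0]], index=["g"])

    def test_bestbin_selects_value(self):
        spec = BinSpec("f", "bestbin", [2])
        assert apply_bin_spec(self.df, spec)["g"] == 9.0

    def test_mean_identity_on_equal_values(self):
        df = pd.DataFrame([[3.0] * 5], index=["g"])
        spec = BinSpec("f", "best5bins", [0, 1, 2, 3, 4])
        assert apply_bin_spec(df, spec)["g"] == 3.0

    def test_out_of_range_index_errors(self):
        with pytest.raises(IndexError):
            apply_bin_spec(self.df, BinSpec("f", "bestbin", [11]))

    def test_empty_spec_rejected_at_construction(self):
        with pytest.raises(ValueError):
            BinSpec("f", "bestbin", [])
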