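"""Interval counting, metaprofiles, ratio tracks, filtering, stratification."""

import numpy as np
import pandas as pd
import pytest

from spikecal import (
    ValidationError,
    count_in_intervals,
    expression_quartiles,
    filter_blacklist,
    ratio_track,
    replicate_correlation,
    rpkm,
    scaled_body_matrix,
    tss_matrix,
)
from spikecal.tracks import CoverageTrack, GeneModel


def ivals(*triples):
    return pd.DataFrame(
        [{"contig": c, "start": s, "end": e} for c, s, e in triples],
        columns=["contig", "start", "end"],
    )


def delta_track(contig_bins=1000, bin_size=10, hot=None, value=100.0):
    data = np.zeros(contig_bins)
    if hot is not None:
        data[hot] = value
    return CoverageTrack({"chrT": data}, bin_size)


class TestCountInIntervals:
    def test_uniform_density_times_length(self, uniform_track):
        out = count_in_intervals(uniform_track, ivals(("chrT", 1000, 1500)))
        assert out.iloc[0] == pytest.approx(500.0)

    def test_empty_track_counts_zero(self):
        out = count_in_intervals(delta_track(), ivals(("chrT", 0, 500)))
        assert out.iloc[0] == 0.0

    def test_half_bin_overlap_is_fractional(self):
        """Interval covering half of a 10 bp bin holding 10 units counts 5."""
        track = delta_track(hot=3, value=10.0)  # bin [30, 40)
        out = count_in_intervals(track, ivals(("chrT", 35, 45)))
        assert out.iloc[0] == pytest.approx(5.0)

    def test_unknown_contig_yields_nan_with_warning(self, uniform_track):
        with pytest.warns(UserWarning, match="unknown contigs"):
            out = count_in_intervals(
                uniform_track, ivals(("chrX", 0, 10), ("chrT", 0, 10))
            )
        assert np.isnan(out.iloc[0]) and out.iloc[1] == pytest.approx(10.0)

    def test_out_of_bounds_clipped_with_warning(self, uniform_track):
        with pytest.warns(UserWarning, match="clipped"):
            out = count_in_intervals(uniform_track, ivals(("chrT", 9000, 20_000)))
        assert out.iloc[0] == pytest.approx(1000.0)


class TestRpkm:
    def test_definitional_value(self):
        assert rpkm([100], [1000], 1e6)[0] == pytest.approx(100.0)

    def test_zero_counts(self):
        assert rpkm([0], [500], 1e6)[0] == 0.0

    def test_arithmetic(self):
        assert rpkm([250], [2500], 2e7)[0] == pytest.approx(5.0)

    @pytest.mark.parametrize("lengths,total", [([0], 1e6), ([100], 0.0)])
    def test_zero_length_or_total_rejected(self, lengths, total):
        with pytest.raises(ValidationError):
            rpkm([1], lengths, total)


class TestTssMatrix:
    def test_delta_at_tss_gives_hot_centre(self):
        track = delta_track(hot=400, value=50.0)  # bin [4000, 4010)
        gene = GeneModel("g", "chrT", "+", tss=4000, tes=6000)
        mat = tss_matrix(track, [gene], flank_bp=100, bin_bp=10)
        row = mat.values[0]
        assert row[10] == pytest.approx(50.0)  # first downstream bin
        assert row.sum() == pytest.approx(50.0)

    def test_constant_track_gives_constant_matrix(self, uniform_track, plus_gene):
        mat = tss_matrix(uniform_track, [plus_gene], flank_bp=200, bin_bp=20)
        np.testing.assert_allclose(mat.values, 20.0)  # 1 unit/bp x 20 bp bins

    def test_minus_strand_signal_downstream_flips(self):
        """Signal 100 bp downstream of a minus-strand TSS (genomic tss-100)
        lands at relative +100 after orientation."""
        # 1 bp bins so the delta sits exactly on one base: genomic 3900
        data = np.zeros(10_000)
        data[3900] = 7.0
        track = CoverageTrack({"chrT": data}, 1)
        gene = GeneModel("g", "chrT", "-", tss=4000, tes=2000)
        mat = tss_matrix(track, [gene], flank_bp=200, bin_bp=10)
        nbins = mat.values.shape[1]
        offsets = (np.arange(nbins)) * 10 - 200  # left edge of each bin
        hot_cols = np.nonzero(mat.values[0] > 0)[0]
        assert len(hot_cols) == 1
        assert offsets[hot_cols[0]] == 100
        assert mat.values[0, hot_cols[0]] == pytest.approx(7.0)

    def test_row_sum_conserves_interval_count(self, toy_tracks):
        """Conservation: row sums equal interval counts over the same window."""
        track = next(iter(toy_tracks.tracks.values()))
        flank = 500
        mat = tss_matrix(track, toy_tracks.genes, flank_bp=flank, bin_bp=10)
        wins = []
        for g in toy_tracks.genes:
            lo, hi = g.window(-flank, flank)
            wins.append(("chrT", lo, hi))
        counts = count_in_intervals(track, ivals(*wins)).to_numpy()
        np.testing.assert_allclose(
            np.nansum(mat.values, axis=1), counts, rtol=1e-6
        )

    def test_strand_symmetry_under_genome_mirroring(self, toy_tracks):
        """Mirroring the contig and flipping every strand leaves profiles
        unchanged."""
        track = next(iter(toy_tracks.tracks.values()))
        arr = track.data["chrT"]
        L = len(arr) * track.bin_size
        mirrored = CoverageTrack({"chrT": arr[::-1].copy()}, track.bin_size)
        flipped = []
        for g in toy_tracks.genes:
            flipped.append(
                GeneModel(
                    g.gene_id,
                    g.contig,
                    "-" if g.strand == "+" else "+",
                    tss=L - 1 - g.tss,
                    tes=L - 1 - g.tes,
                )
            )
        a = tss_matrix(track, toy_tracks.genes, flank_bp=500, bin_bp=10)
        b = tss_matrix(mirrored, flipped, flank_bp=500, bin_bp=10)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-9, atol=1e-9)

    def test_flank_not_multiple_of_bin_rejected(self, uniform_track, plus_gene):
        with pytest.raises(ValidationError):
            tss_matrix(uniform_track, [plus_gene], flank_bp=105, bin_bp=10)

    def test_off_contig_padding_is_nan(self, uniform_track):
        gene = GeneModel("g", "chrT", "+", tss=50, tes=2000)
        mat = tss_matrix(uniform_track, [gene], flank_bp=200, bin_bp=10)
        assert np.isnan(mat.values[0, :15]).all()
        assert np.isfinite(mat.values[0, 20:]).all()


class TestScaledBodyMatrix:
    def test_constant_track_gives_flat_density(self, uniform_track, plus_gene):
        mat = scaled_body_matrix(uniform_track, [plus_gene], nbins=50, flank_bp=200)
        np.testing.assert_allclose(mat.values[0], 1.0)

    def test_scale_invariance_across_gene_lengths(self):
        """Two genes with identical relative signal shape but 1 kb vs 10 kb
        length give identical rows."""
        bin_size = 10
        data = np.zeros(3000)
        g1 = GeneModel("g1", "chrT", "+", tss=2000, tes=3000)
        g2 = GeneModel("g2", "chrT", "+", tss=10_000, tes=20_000)
        # same relative shape: first 20% of the body at density 5, rest at 1
        for g in (g1, g2):
            body = g.length
            s = g.tss // bin_size
            k = int(0.2 * body) // bin_size
            data[s : s + k] = 5.0 * bin_size
            data[s + k : (g.tes // bin_size)] = 1.0 * bin_size
        track = CoverageTrack({"chrT": data}, bin_size)
        mat = scaled_body_matrix(track, [g1, g2], nbins=10, flank_bp=100, flank_bins=10)
        fb = 10
        np.testing.assert_allclose(
            mat.values[0, fb:-fb], mat.values[1, fb:-fb], rtol=1e-9
        )

    def test_single_bin_equals_mean_body_density(self, uniform_track, plus_gene):
        mat = scaled_body_matrix(uniform_track, [plus_gene], nbins=1, flank_bp=100)
        assert mat.values[0][mat.meta["flank_bins"]] == pytest.approx(1.0)

    def test_short_genes_excluded_with_count(self, uniform_track):
        short = GeneModel("s", "chrT", "+", tss=100, tes=140)
        long = GeneModel("l", "chrT", "+", tss=2000, tes=6000)
        mat = scaled_body_matrix(uniform_track, [short, long], nbins=100, flank_bp=100)
        assert mat.meta["n_excluded"] == 1
        assert mat.region_ids == ["l"]


class TestRatioTrack:
    def test_identity(self, uniform_track):
        out = ratio_track(uniform_track, uniform_track, pseudocount=0.0)
        np.testing.assert_allclose(out.data["chrT"], 1.0)

    def test_double_numerator(self, uniform_track):
        out = ratio_track(uniform_track.scaled(2.0), uniform_track, pseudocount=0.0)
        np.testing.assert_allclose(out.data["chrT"], 2.0)

    def test_pseudocount_arithmetic(self):
        num = CoverageTrack({"c": np.array([0.0])}, 1)
        den = CoverageTrack({"c": np.array([9.0])}, 1)
        out = ratio_track(num, den, pseudocount=1.0)
        assert out.data["c"][0] == pytest.approx(0.1)

    def test_swapped_ratios_multiply_to_one(self, toy_tracks):
        names = list(toy_tracks.tracks)
        a = toy_tracks.tracks[names[0]].scaled(1.0)
        b = toy_tracks.tracks[names[-1]].scaled(1.0)
        # keep strictly positive bins so the pc=0 ratio is defined
        a = CoverageTrack({"chrT": a.data["chrT"] + 1.0}, a.bin_size)
        b = CoverageTrack({"chrT": b.data["chrT"] + 1.0}, b.bin_size)
        fwd = ratio_track(a, b, pseudocount=0.0)
        rev = ratio_track(b, a, pseudocount=0.0)
        np.testing.assert_allclose(fwd.data["chrT"] * rev.data["chrT"], 1.0, rtol=1e-12)

    def test_mismatched_bins_rejected(self, uniform_track):
        other = CoverageTrack({"chrT": np.ones(500)}, 20)
        with pytest.raises(ValidationError):
            ratio_track(uniform_track, other)


class TestBlacklist:
    def test_empty_blacklist_is_identity(self):
        reads = ivals(("chrT", 0, 50), ("chrT", 100, 150))
        out = filter_blacklist(reads, ivals())
        assert len(out) == 2

    def test_contained_read_removed(self):
        out = filter_blacklist(
            ivals(("chrT", 100, 150)), ivals(("chrT", 50, 200))
        )
        assert len(out) == 0

    def test_abutting_read_retained_half_open(self):
        """Read ending exactly where the blacklist starts does not overlap."""
        out = filter_blacklist(
            ivals(("chrT", 50, 100), ("chrT", 100, 150)),
            ivals(("chrT", 100, 120)),
        )
        assert list(out["start"]) == [50]

    def test_single_bp_overlap_removed(self):
        out = filter_blacklist(
            ivals(("chrT", 50, 101)), ivals(("chrT", 100, 120))
        )
        assert len(out) == 0


class TestReplicateCorrelation:
    def test_identical_replicates_perfect(self):
        df = pd.DataFrame({"r1": [1, 5, 9, 2.0], "r2": [1, 5, 9, 2.0]})
        r, gate = replicate_correlation(df)
        assert r.loc["r1", "r2"] == pytest.approx(1.0)
        assert gate

    def test_negated_replicate(self):
        df = pd.DataFrame({"r1": [1, 5, 9, 2.0], "r2": [-1, -5, -9, -2.0]})
        r, gate = replicate_correlation(df)
        assert r.loc["r1", "r2"] == pytest.approx(-1.0)
        assert not gate

    def test_zero_variance_gives_nan_warning(self):
        df = pd.DataFrame({"r1": [1, 1, 1.0], "r2": [1, 2, 3.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            r, gate = replicate_correlation(df)
        assert np.isnan(r.loc["r1", "r2"])
        assert not gate

    def test_simulated_replicates_pass_gate(self, small_sim):
        cond = small_sim.assay.samples["condition"]
        reps = small_sim.assay.target_counts.loc[:, (cond == "UNT").to_numpy()]
        r, gate = replicate_correlation(reps, threshold=0.95)
        assert gate


class TestQuartiles:
    def test_eight_distinct_values_two_per_quartile(self):
        s = pd.Series([3, 1, 4, 1.5, 9, 2.6, 5, 3.5], index=list("abcdefgh"))
        q = expression_quartiles(s)
        assert q.value_counts().eq(2).all()
        assert q["e"] == "Q4" and q["b"] == "Q1"

    def test_all_equal_values_stable_order_balanced(self):
        s = pd.Series([7.0] * 10, index=[f"g{i}" for i in range(10)])
        q = expression_quartiles(s)
        sizes = q.value_counts()
        assert sizes.max() - sizes.min() <= 1
        assert q["g0"] == "Q1" and q["g9"] == "Q4"  # stable id order

    def test_max_value_in_top_quartile(self):
        s = pd.Series(np.arange(1, 101, dtype=float))
        q = expression_quartiles(s)
        assert q.iloc[-1] == "Q4"

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValidationError):
            expression_quartiles(pd.Series([1.0, 2.0, 3.0]))
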