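"""Background model, signal partition, profiles, vectors and end calls."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_catalog, make_track, make_transcript
from zedsense.chip import (
    classify_occupancy,
    cluster_profiles,
    end_enrichment_frame,
    feature_vector,
    metagene_profile,
    normalize_rpm,
    occupancy_vectors,
    partition_signal,
    quantify_end_enrichment,
    subtract_background,
)


def signal_from_arrays(chip_values, input_values):
    chip = make_track(chip_values, total_mapped=1e6)
    inp = make_track(input_values, total_mapped=1e6)
    return subtract_background(chip, inp)


def flat_signal(values):
    """SignalTrack with given per-bp values (bypasses the ratio model)."""
    sig = signal_from_arrays(np.zeros(len(values)), np.ones(len(values)))
    sig.values["chrI"] = np.asarray(values, dtype=float)
    return sig


class TestNormalizeRPM:
    def test_identity_at_one_million_reads(self):
        track = make_track([1.0, 2.0], total_mapped=1e6)
        np.testing.assert_array_equal(normalize_rpm(track).values["chrI"], [1.0, 2.0])

    def test_scaling(self):
        track = make_track([5.0], total_mapped=2e6)
        assert normalize_rpm(track).values["chrI"][0] == pytest.approx(2.5)

    def test_total_conservation(self):
        rng = np.random.default_rng(0)
        track = make_track(rng.random(100), total_mapped=3.3e6)
        before = track.total()
        assert normalize_rpm(track).total() == pytest.approx(before * 1e6 / 3.3e6)

    def test_zero_mapped_rejected(self):
        with pytest.raises(ValueError):
            normalize_rpm(make_track([1.0], total_mapped=0))


class TestSubtractBackground:
    def test_hand_computed_moments(self):
        """ratios [1,1,1,11]: mean 3.5, sample SD 5, B = 9.5, signal 1.5."""
        sig = signal_from_arrays([1, 1, 1, 11], [1, 1, 1, 1])
        assert sig.ratio_mean == pytest.approx(3.5)
        assert sig.ratio_sd == pytest.approx(5.0)
        assert sig.background == pytest.approx(9.5)
        np.testing.assert_allclose(sig.values["chrI"], [0, 0, 0, 1.5])

    def test_constant_ratio_yields_zero_signal(self):
        sig = signal_from_arrays([2, 2, 2, 2], [1, 1, 1, 1])
        assert sig.ratio_sd == 0
        assert sig.background == pytest.approx(sig.ratio_mean)
        assert sig.total() == 0

    def test_zero_input_positions_masked(self):
        sig = signal_from_arrays([5, 1, 1, 11], [0, 1, 1, 1])
        # moments over unmasked ratios [1, 1, 11] only
        assert sig.ratio_mean == pytest.approx(13 / 3)
        assert sig.values["chrI"][0] == 0.0

    def test_all_masked_is_an_error(self):
        with pytest.raises(ValueError, match="no usable input"):
            signal_from_arrays([1, 1], [0, 0])

    def test_k_zero_symmetric_noise_zeroes_half(self):
        """With k=0, B is the ratio mean; an exactly symmetric ratio sample
        leaves exactly half of the positions positive."""
        rng = np.random.default_rng(1)
        half = 1 + 0.5 * rng.random(500)
        ratios = np.concatenate([half, 2 - half])  # antithetic: mean exactly 1... times scale
        chip = make_track(ratios, total_mapped=1e6)
        inp = make_track(np.ones(1000), total_mapped=1e6)
        sig = subtract_background(chip, inp, k=0.0)
        assert (sig.values["chrI"] > 0).sum() == 500

    def test_floor_reapplication_changes_nothing(self):
        """An all-zero signal re-subtracted with k=0 stays all zero."""
        zero_chip = make_track(np.zeros(50), total_mapped=1e6)
        inp = make_track(np.ones(50), total_mapped=1e6)
        sig = subtract_background(zero_chip, inp, k=0.0)
        assert sig.total() == 0


class TestPartition:
    def test_all_signal_in_tss_window(self):
        cat = make_catalog([make_transcript("g", 1000, 2000, "+")], {"chrI": 3000})
        values = np.zeros(3000)
        values[900:1100] = 1.0  # inside TSS +/- 300
        part = partition_signal(flat_signal(values), cat)
        assert part.percent("five_prime") == pytest.approx(100.0)

    def test_gene_free_chromosome_is_igr(self):
        cat = make_catalog(
            [make_transcript("g", 1000, 2000, "+", chrom="chrI")],
            {"chrI": 3000, "chrII": 1000},
        )
        values = {"chrI": np.zeros(3000), "chrII": np.ones(1000)}
        sig = flat_signal(np.zeros(3000))
        sig.values = values
        part = partition_signal(sig, cat)
        assert part.percent("igr") == pytest.approx(100.0)

    def test_percents_sum_to_100(self, paper_sim):
        part = partition_signal(paper_sim["signal"], paper_sim["catalog"])
        assert part.table["percent"].sum() == pytest.approx(100.0)

    def test_three_prime_share_tracks_planted_peaks(self, paper_sim):
        """With ~20% of genes carrying a 3' peak (about half the rate of 5'
        peaks, one bump vs two), the 3'-end share of total signal is
        substantial but below the 5' share."""
        part = partition_signal(paper_sim["signal"], paper_sim["catalog"])
        assert part.percent("five_prime") > part.percent("three_prime") > 5.0

    def test_empty_catalog_rejected(self):
        cat = make_catalog(
            [make_transcript("n", 0, 100, "+", kind="noncoding")], {"chrI": 1000}
        )
        with pytest.raises(ValueError):
            partition_signal(flat_signal(np.zeros(1000)), cat)


class TestMetagene:
    def test_delta_spike_appears_at_its_offset(self):
        cat = make_catalog([make_transcript("g", 1000, 2000, "+")], {"chrI": 3000})
        values = np.zeros(3000)
        values[1010] = 7.0
        prof = metagene_profile(flat_signal(values), cat, "tss_aligned", span=50)
        df = prof.to_frame().set_index("position")
        assert df.loc[10, "mean"] == pytest.approx(7.0)
        assert df.drop(10)["mean"].sum() == 0

    def test_mirror_strands_give_identical_profiles(self):
        chrom_len = 3000
        plus = make_transcript("p", 1000, 2000, "+")
        minus = make_transcript("m", chrom_len - 2000, chrom_len - 1000, "-")
        values = np.zeros(chrom_len)
        values[1005] = 3.0
        mirror = np.zeros(chrom_len)
        mirror[chrom_len - 1 - 1005] = 3.0
        cat_p = make_catalog([plus], {"chrI": chrom_len})
        cat_m = make_catalog([minus], {"chrI": chrom_len})
        prof_p = metagene_profile(flat_signal(values), cat_p, "tss_aligned", span=20)
        prof_m = metagene_profile(flat_signal(mirror), cat_m, "tss_aligned", span=20)
        np.testing.assert_allclose(prof_p.mean, prof_m.mean)

    def test_scaled_cds_ramp_recovers_ramp(self):
        """A 0->1 linear ramp over each gene body averages to a 0->1 ramp
        over the scaled bins, within interpolation error."""
        genes = [
            make_transcript("a", 1000, 3000, "+"),
            make_transcript("b", 4000, 7000, "-"),
        ]
        cat = make_catalog(genes, {"chrI": 9000})
        values = np.zeros(9000)
        for g in genes:
            ramp = np.linspace(0, 1, g.length)
            seg = ramp if g.strand == "+" else ramp[::-1]
            values[g.interval.start:g.interval.end] = seg
        prof = metagene_profile(flat_signal(values), cat, "scaled_cds", n_bins=20)
        expected = np.linspace(0, 1, 22)[1:-1]  # interior of the ramp
        assert np.max(np.abs(prof.mean - expected)) < 0.2
        assert np.all(np.diff(prof.mean) > 0)

    def test_no_eligible_genes_rejected(self):
        cat = make_catalog([make_transcript("g", 0, 500, "+")], {"chrI": 1000})
        with pytest.raises(ValueError):
            metagene_profile(flat_signal(np.zeros(1000)), cat, "scaled_cds", n_bins=5)


class TestFeatureVector:
    def test_zero_signal_gives_zero_vector(self):
        t = make_transcript("g", 1000, 2000, "+")
        np.testing.assert_array_equal(
            feature_vector(flat_signal(np.zeros(3000)), t, 3000), np.zeros(25)
        )

    def test_constant_signal_fills_all_entries(self):
        t = make_transcript("g", 1000, 2000, "+")
        vec = feature_vector(flat_signal(np.full(3000, 2.5)), t, 3000)
        np.testing.assert_allclose(vec, 2.5)

    def test_spike_lands_in_first_tes_window(self):
        """Mass m in [tes-150, tes-100) fills entry index 19 with m/50."""
        t = make_transcript("g", 1000, 2000, "+")
        values = np.zeros(3000)
        values[1850:1900] = 4.0  # mass 200 over the 50-bp window
        vec = feature_vector(flat_signal(values), t, 3000)
        assert vec[19] == pytest.approx(4.0)
        others = np.delete(vec, 19)
        np.testing.assert_allclose(others, 0.0)

    def test_minus_strand_spike_symmetry(self):
        t = make_transcript("g", 1000, 2000, "-")
        values = np.zeros(3000)
        values[1100:1150] = 4.0  # [tes+100... in transcription direction: first TES window
        vec = feature_vector(flat_signal(values), t, 3000)
        assert vec[19] == pytest.approx(4.0)

    def test_short_transcript_rejected(self):
        t = make_transcript("g", 0, 300, "+")
        with pytest.raises(ValueError, match="too short"):
            feature_vector(flat_signal(np.zeros(1000)), t, 1000)

    def test_consistent_with_single_gene_metagene(self):
        """On a one-gene catalog, TSS/TES window means equal the averages of
        the corresponding metagene offsets."""
        t = make_transcript("g", 1000, 2000, "+")
        cat = make_catalog([t], {"chrI": 3000})
        rng = np.random.default_rng(2)
        sig = flat_signal(rng.random(3000))
        vec = feature_vector(sig, t, 3000)
        tss_prof = metagene_profile(sig, cat, "tss_aligned", span=300).mean
        for j in range(9):  # window j covers offsets [-300+50j, -250+50j)
            assert vec[j] == pytest.approx(tss_prof[50 * j: 50 * (j + 1)].mean())


class TestClustering:
    def test_planted_groups_recovered(self):
        rng = np.random.default_rng(3)
        five_only = np.tile(np.r_[np.full(9, 5.0), np.zeros(16)], (10, 1))
        three_only = np.tile(np.r_[np.zeros(19), np.full(6, 5.0)], (10, 1))
        mat = np.vstack([five_only, three_only]) + rng.normal(0, 0.1, (20, 25))
        vectors = pd.DataFrame(mat, index=[f"g{i:02d}" for i in range(20)])
        labels, _ = cluster_profiles(vectors, 2)
        assert labels.iloc[:10].nunique() == 1
        assert labels.iloc[10:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[10]

    def test_identical_vectors_single_cluster(self):
        vectors = pd.DataFrame(np.ones((5, 25)), index=list("abcde"))
        labels, z = cluster_profiles(vectors, 1)
        assert labels.nunique() == 1
        assert z[:, 2].max() == 0.0

    def test_input_order_invariance(self):
        rng = np.random.default_rng(4)
        vectors = pd.DataFrame(rng.random((12, 25)), index=[f"g{i}" for i in range(12)])
        l1, _ = cluster_profiles(vectors, 3)
        l2, _ = cluster_profiles(vectors.iloc[::-1], 3)
        assert (l1.sort_index() == l2.sort_index()).all()

    def test_too_many_clusters_rejected(self):
        vectors = pd.DataFrame(np.ones((3, 25)))
        with pytest.raises(ValueError):
            cluster_profiles(vectors, 5)


class TestEndEnrichment:
    def test_zero_signal_zero_levels(self):
        cat = make_catalog([make_transcript("g", 0, 1000, "+")], {"chrI": 2000})
        enr = quantify_end_enrichment(flat_signal(np.zeros(2000)), cat)
        assert enr[0].five_prime_level == 0 and enr[0].three_prime_level == 0
        assert enr[0].three_call == "none"

    def test_three_prime_only_signal(self):
        cat = make_catalog([make_transcript("g", 0, 1000, "+")], {"chrI": 2000})
        values = np.zeros(2000)
        values[850:1000] = 2.0
        enr = quantify_end_enrichment(flat_signal(values), cat)
        assert enr[0].three_prime_level == pytest.approx(2.0)
        assert enr[0].five_prime_level == 0.0

    def test_levels_scale_linearly(self, paper_sim):
        sig = paper_sim["signal"]
        cat = paper_sim["catalog"]
        enr1 = quantify_end_enrichment(sig, cat)
        scaled = flat_signal(np.zeros(10))
        scaled.values = {c: 3.0 * a for c, a in sig.values.items()}
        enr2 = quantify_end_enrichment(scaled, cat)
        r1 = np.array([e.three_prime_level for e in enr1])
        r2 = np.array([e.three_prime_level for e in enr2])
        np.testing.assert_allclose(r2, 3.0 * r1, rtol=1e-12)
        # calls are scale invariant
        assert [e.three_call for e in enr1] == [e.three_call for e in enr2]

    def test_planted_peak_recovery(self, paper_sim):
        """High-3' calls recover the planted 3' peaks with sensitivity and
        specificity both at least 0.9."""
        df = end_enrichment_frame(paper_sim["enrichment"]).join(
            paper_sim["truth"].genes
        )
        truth_pos = df["has_3prime_peak"]
        sens = (df.loc[truth_pos, "three_call"] == "high").mean()
        spec = (df.loc[~truth_pos, "three_call"] != "high").mean()
        assert sens >= 0.9
        assert spec >= 0.9


class TestClassifyOccupancy:
    def test_zero_vs_positive_mean(self):
        assert classify_occupancy([0, 0, 4, 4]) == ["none", "none", "high", "high"]

    def test_intermediate_band(self):
        assert classify_occupancy([0, 1, 3, 8]) == [
            "none",
            "intermediate",
            "intermediate",
            "high",
        ]

    def test_scale_invariance(self):
        levels = [0.0, 0.5, 2.0, 9.0]
        assert classify_occupancy(levels) == classify_occupancy([7 * v for v in levels])

    def test_negative_levels_rejected(self):
        with pytest.raises(ValueError):
            classify_occupancy([-1.0, 2.0])
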