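"""Generator contracts: determinism, calibration, geometry, count model."""

import dataclasses

import numpy as np
import pytest

from zedsense.diffexpr import test_differential as nb_differential_test
from zedsense.genome import region_of
from zedsense.simulate import (
    SimulationConfig,
    simulate_chip,
    simulate_genome,
    simulate_rna,
)


def small_config(**kw):
    defaults = dict(n_genes=200, seed=123)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            small_config(fraction_tandem_close=0.9)

    def test_probabilities_bounded(self):
        with pytest.raises(ValueError):
            small_config(p_5prime_peak=1.5)

    def test_positive_dispersion_and_folds(self):
        with pytest.raises(ValueError):
            small_config(dispersion=0.0)
        with pytest.raises(ValueError):
            small_config(effect_down_as=-1.0)

    def test_yaml_round_trip(self):
        cfg = small_config()
        assert SimulationConfig.from_dict(cfg.to_dict()) == cfg


class TestGenomeGeometry:
    def test_too_small_chromosome_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            simulate_genome(small_config(chrom_length=10_000))

    def test_all_tandem_close_means_small_same_strand_gaps(self):
        cfg = small_config(
            fraction_tandem_close=1.0,
            fraction_tandem_far=0.0,
            fraction_convergent_close=0.0,
            fraction_convergent_far=0.0,
        )
        catalog, truth = simulate_genome(cfg)
        genes = catalog.coding()
        for g1, g2 in zip(genes, genes[1:]):
            assert g1.strand == g2.strand
            assert 0 < g2.interval.start - g1.interval.end < 300

    def test_antisense_iff_three_prime_peak_when_forced(self):
        cfg = small_config(p_antisense_given_3peak=1.0, p_antisense_given_no3peak=0.0)
        _, truth = simulate_genome(cfg)
        assert (truth.genes["has_antisense"] == truth.genes["has_3prime_peak"]).all()

    def test_antisense_rates_within_binomial_error(self, paper_sim):
        """Realised antisense incidence matches the 0.52 / 0.05 programmed
        rates within 3 binomial standard errors over 4000 genes."""
        genes = paper_sim["truth"].genes
        for flag, p in ((True, 0.52), (False, 0.05)):
            sub = genes[genes["has_3prime_peak"] == flag]
            n = len(sub)
            se = np.sqrt(p * (1 - p) / n)
            assert abs(sub["has_antisense"].mean() - p) < 3 * se

    def test_antisense_geometry(self, paper_sim):
        """Every antisense transcript starts inside its host's 3'-inner
        window, on the opposite strand, within the host span."""
        catalog = paper_sim["catalog"]
        truth = paper_sim["truth"]
        hosts = truth.antisense_hosts()
        for t in catalog.noncoding():
            host = catalog.by_id(hosts[t.id])
            assert t.strand != host.strand
            win = region_of(host, "three_prime_inner", 150)
            assert win.start <= t.tss < win.end or t.tss == win.end
            assert t.interval.overlap(host.interval) == t.length

    def test_determinism(self):
        c1, t1 = simulate_genome(small_config())
        c2, t2 = simulate_genome(small_config())
        assert [t.interval for t in c1] == [t.interval for t in c2]
        assert t1.genes.equals(t2.genes)
        c3, _ = simulate_genome(small_config(seed=124))
        assert [t.interval for t in c3] != [t.interval for t in c1]


class TestChipSim:
    def test_same_seed_identical_different_seed_not(self):
        cfg = small_config()
        catalog, truth = simulate_genome(cfg)
        chip1, inp1 = simulate_chip(catalog, truth, cfg)
        chip2, inp2 = simulate_chip(catalog, truth, cfg)
        np.testing.assert_array_equal(chip1.values["chrSim"], chip2.values["chrSim"])
        cfg2 = dataclasses.replace(cfg, seed=999)
        chip3, _ = simulate_chip(catalog, truth, cfg2)
        assert not np.array_equal(chip3.values["chrSim"], chip1.values["chrSim"])

    def test_zero_peak_height_means_no_systematic_signal(self):
        cfg = small_config(chip_peak_height=0.0)
        catalog, truth = simulate_genome(cfg)
        chip, inp = simulate_chip(catalog, truth, cfg)
        ratio = chip.values["chrSim"] / inp.values["chrSim"]
        assert abs(ratio.mean() - 1.0) < 0.05

    def test_single_gene_peak_argmax_in_three_prime_window(self):
        cfg = SimulationConfig(
            n_genes=2, seed=7, p_5prime_peak=0.0,
            p_3prime_peak_tandem=1.0, p_3prime_peak_convergent=1.0,
            chip_noise_sd=0.5,
        )
        catalog, truth = simulate_genome(cfg)
        chip, inp = simulate_chip(catalog, truth, cfg)
        ratio = chip.values["chrSim"] / inp.values["chrSim"]
        g = catalog.coding()[0]
        win = region_of(g, "three_prime_inner", 150, catalog.chrom_sizes["chrSim"])
        # argmax restricted to this gene's neighbourhood
        lo, hi = g.interval.start, g.interval.end + 300
        peak_pos = lo + int(np.argmax(ratio[lo:hi]))
        assert win.start <= peak_pos < win.end


class TestRnaSim:
    def test_counts_concentrate_at_programmed_mean_when_dispersion_vanishes(self):
        cfg = small_config(
            n_genes=50, dispersion=1e-6, n_replicates=50,
            p_antisense_given_3peak=0.0, p_antisense_given_no3peak=0.0,
        )
        catalog, truth = simulate_genome(cfg)
        rna = simulate_rna(catalog, truth, cfg, tracks_for=[])
        base_cols = [c for c in rna.counts.columns if c.startswith("rrp6d_rep")]
        sample_means = rna.counts[base_cols].mean(axis=1)
        # with the NB overdispersion switched off only Poisson noise remains:
        # the pooled mean converges and each transcript stays within a few
        # counting-noise standard errors of the programmed mean
        assert sample_means.mean() == pytest.approx(cfg.rna_mean_sense, rel=0.02)
        assert (abs(sample_means - cfg.rna_mean_sense) / cfg.rna_mean_sense < 0.06).all()

    def test_null_configuration_false_positive_rate(self):
        """With both effects at 1 the two conditions are exchangeable; the
        DE stand-in's false-positive rate stays below 2x alpha."""
        cfg = SimulationConfig(
            n_genes=1800, seed=21, effect_down_as=1.0, effect_sense_coupling=1.0
        )
        catalog, truth = simulate_genome(cfg)
        rna = simulate_rna(catalog, truth, cfg, tracks_for=[])
        de = nb_differential_test(rna.counts, rna.design, alpha=0.05)
        assert (de["pvalue"] < 0.05).mean() <= 0.10

    def test_antisense_counts_on_opposite_strand_only(self):
        cfg = small_config()
        catalog, truth = simulate_genome(cfg)
        rna = simulate_rna(catalog, truth, cfg, tracks_for=[("rrp6d", "rep1")])
        expr = rna.expressions[("rrp6d", "rep1")]
        col = "rrp6d_rep1"
        for t in catalog.noncoding():
            count = rna.counts.loc[t.id, col]
            if count == 0:
                continue
            own = expr.track_for(t.strand).sum_over(t.interval)
            assert own > 0
            host = catalog.by_id(truth.antisense_hosts()[t.id])
            assert host.strand != t.strand

    def test_condition_two_applies_programmed_folds(self):
        cfg = small_config(n_genes=400, dispersion=1e-6, n_replicates=3)
        catalog, truth = simulate_genome(cfg)
        rna = simulate_rna(catalog, truth, cfg, tracks_for=[])
        cols2 = [c for c in rna.counts.columns if c.startswith("rrp6d_htz1d")]
        affected = truth.genes[truth.genes["has_antisense"] & truth.genes["has_3prime_peak"]]
        assert len(affected) > 10
        as_mean = rna.counts.loc[affected["antisense_id"], cols2].to_numpy().mean()
        assert as_mean == pytest.approx(cfg.rna_mean_antisense * cfg.effect_down_as, rel=0.1)
        sense_mean = rna.counts.loc[affected.index, cols2].to_numpy().mean()
        assert sense_mean == pytest.approx(cfg.rna_mean_sense * cfg.effect_sense_coupling, rel=0.05)
        unaffected = truth.genes[~truth.genes["has_3prime_peak"]]
        base_mean = rna.counts.loc[unaffected.index, cols2].to_numpy().mean()
        assert base_mean == pytest.approx(cfg.rna_mean_sense, rel=0.05)
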