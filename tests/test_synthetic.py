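"""Generator checks: Mendelian segregation, Haldane linkage, read noise,
phenotype structure and fixture determinism."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gbsmap.config import SimulationConfig
from gbsmap import synthetic

from conftest import two_marker_map


def _cross(cfg, seed=None):
    rng = np.random.default_rng(cfg.random_seed if seed is None else seed)
    mm = synthetic.build_marker_map(cfg, rng)
    return mm, synthetic.simulate_cross(mm, cfg, rng), rng


class TestSimulateCross:
    def test_allele_b_frequency_in_ab_x_aa_cross(self):
        # one het parent: allele b expected in half the parent-1 gametes,
        # i.e. at frequency 1/4 among all progeny alleles
        mm = two_marker_map(0.0)
        cfg = SimulationConfig(n_progeny=10_000, qtl_marker_id=None, random_seed=5)
        geno = synthetic.simulate_cross(mm, cfg, np.random.default_rng(5))
        n_alleles = 2 * cfg.n_progeny
        freq_b = geno.genotypes.loc[geno.progeny_ids, "m1"].str.count("G").sum() / n_alleles
        se = np.sqrt(0.25 * 0.75 / n_alleles)
        assert abs(freq_b - 0.25) < 3 * se

    @pytest.mark.parametrize("d_cm,expected_r", [(0.0, 0.0), (20.0, 0.5 * (1 - np.exp(-0.4)))])
    def test_haldane_recombinant_fraction(self, d_cm, expected_r):
        mm = two_marker_map(d_cm)
        cfg = SimulationConfig(n_progeny=10_000, qtl_marker_id=None, random_seed=9)
        geno = synthetic.simulate_cross(mm, cfg, np.random.default_rng(9))
        # parent 1 is A/G at both markers: its transmitted alleles reveal
        # the haplotype; a switch between markers is a recombinant gamete
        g = geno.from_parent1
        recomb = (g["m1"] != g["m2"]).mean()
        if d_cm == 0:
            assert recomb == 0.0
        else:
            se = np.sqrt(expected_r * (1 - expected_r) / cfg.n_progeny)
            assert abs(recomb - expected_r) < 3 * se

    def test_mendelian_1_to_1_segregation(self):
        mm = two_marker_map(0.0)
        cfg = SimulationConfig(n_progeny=2_000, qtl_marker_id=None, random_seed=13)
        geno = synthetic.simulate_cross(mm, cfg, np.random.default_rng(13))
        counts = geno.genotypes.loc[geno.progeny_ids, "m1"].value_counts()
        chi2 = stats.chisquare([counts.get("A/A", 0), counts.get("A/G", 0)])
        assert chi2.pvalue > 0.001

    def test_progeny_alleles_come_from_parents(self, small_cross):
        mm, geno = small_cross
        t = mm.table.set_index("marker_id")
        for marker_id in mm.marker_ids:
            allowed1 = set(t.loc[marker_id, "parent1_gt"].split("/"))
            allowed2 = set(t.loc[marker_id, "parent2_gt"].split("/"))
            assert set(geno.from_parent1[marker_id]) <= allowed1
            assert set(geno.from_parent2[marker_id]) <= allowed2

    def test_empty_chromosome_rejected(self):
        cfg = SimulationConfig(markers_per_chromosome=0, qtl_marker_id=None)
        with pytest.raises(ValueError):
            synthetic.build_marker_map(cfg)

    def test_linkage_decays_with_map_distance(self):
        # average estimated recombination fraction over 20 replicates is
        # monotone non-decreasing in map distance
        distances = [2.0, 10.0, 30.0]
        means = []
        for d in distances:
            mm = two_marker_map(d)
            cfg = SimulationConfig(n_progeny=200, qtl_marker_id=None)
            r_hats = []
            for rep in range(20):
                geno = synthetic.simulate_cross(mm, cfg, np.random.default_rng(100 + rep))
                g = geno.from_parent1
                r_hats.append((g["m1"] != g["m2"]).mean())
            means.append(np.mean(r_hats))
        assert means == sorted(means)


class TestSimulateObservations:
    def test_error_free_reads_only_show_true_alleles(self):
        mm = two_marker_map(0.0)
        cfg = SimulationConfig(n_progeny=10, base_error_rate=0.0,
                               qtl_marker_id=None, random_seed=3)
        geno = synthetic.simulate_cross(mm, cfg, np.random.default_rng(3))
        obs = synthetic.simulate_observations(geno, cfg, np.random.default_rng(3))
        pos_to_marker = dict(zip(mm.table["pos_bp"], mm.table["marker_id"]))
        for (sample, pos), grp in obs.groupby(["sample_id", "pos"]):
            truth = set(geno.genotypes.loc[sample, pos_to_marker[pos]].split("/"))
            assert set(grp["allele"]) <= truth
            if len(truth) == 1:  # homozygote: reads are 100% one allele
                assert grp["allele"].nunique() == 1

    def test_zero_depth_gives_empty_observations(self, small_cross):
        mm, geno = small_cross
        cfg = SimulationConfig(n_progeny=30, mean_depth=0.0, qtl_marker_id=None)
        obs = synthetic.simulate_observations(geno, cfg, np.random.default_rng(0))
        assert len(obs) == 0

    def test_heterozygote_allele_fraction_near_half(self):
        mm = two_marker_map(0.0)
        cfg = SimulationConfig(n_progeny=2, base_error_rate=0.0, mean_depth=5_000,
                               qtl_marker_id=None, random_seed=17)
        geno = synthetic.simulate_cross(mm, cfg, np.random.default_rng(17))
        obs = synthetic.simulate_observations(geno, cfg, np.random.default_rng(17))
        # parent 1 is A/G: pool its observations at both markers
        par = obs[obs["sample_id"] == "Idared"]
        n = len(par)
        frac_a = (par["allele"] == "A").mean()
        assert abs(frac_a - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_offsets_and_phred_ranges(self, small_cross, small_cfg):
        mm, geno = small_cross
        obs = synthetic.simulate_observations(geno, small_cfg, np.random.default_rng(8))
        assert obs["offset_start"].between(1, small_cfg.read_length).all()
        assert (obs["offset_end"] == small_cfg.read_length - obs["offset_start"] + 1).all()
        low = (obs["phred"] < 20).mean()
        assert 0.02 < low < 0.09  # around the configured 5%


class TestSimulatePhenotypes:
    def test_zero_sd_gives_exact_means(self, small_cross, small_cfg):
        mm, geno = small_cross
        cfg = dataclasses.replace(small_cfg, phenotype_sd=0.0, missing_shoot_rate=0.0)
        pheno = synthetic.simulate_phenotypes(geno, cfg, np.random.default_rng(1))
        pll = 100 * pheno["necrosis_length_mm"] / pheno["shoot_length_mm"]
        carriers = geno.carriers(cfg.qtl_marker_id)
        carrier_ids = set(carriers.index[carriers])
        is_c = pheno["genotype_id"].isin(carrier_ids | {"Jackii"})
        # lengths are reported to 0.01 mm, so PLL is exact to ~0.01%
        assert np.allclose(pll[is_c], cfg.qtl_carrier_mean_pll, atol=0.01)
        assert np.allclose(pll[~is_c], cfg.qtl_noncarrier_mean_pll, atol=0.01)

    def test_group_means_recovered(self):
        cfg = SimulationConfig(n_progeny=119, n_chromosomes=3,
                               markers_per_chromosome=8, random_seed=23)
        rng = np.random.default_rng(23)
        mm = synthetic.build_marker_map(cfg, rng)
        geno = synthetic.simulate_cross(mm, cfg, rng)
        pheno = synthetic.simulate_phenotypes(geno, cfg, rng)
        pheno = pheno[~pheno["genotype_id"].isin(geno.parent_ids)]
        pll = 100 * pheno["necrosis_length_mm"] / pheno["shoot_length_mm"]
        carriers = geno.carriers(cfg.qtl_marker_id)
        is_c = pheno["genotype_id"].map(carriers)
        for mask, mean in [(is_c, cfg.qtl_carrier_mean_pll),
                           (~is_c, cfg.qtl_noncarrier_mean_pll)]:
            vals = pll[mask.to_numpy()]
            se = cfg.phenotype_sd / np.sqrt(len(vals))
            assert abs(vals.mean() - mean) < 3 * se

    def test_all_missing_gives_empty_table(self, small_cross, small_cfg):
        mm, geno = small_cross
        cfg = dataclasses.replace(small_cfg, missing_shoot_rate=1.0)
        pheno = synthetic.simulate_phenotypes(geno, cfg, np.random.default_rng(1))
        assert len(pheno) == 0

    def test_pll_bounded(self, small_cross, small_cfg):
        mm, geno = small_cross
        pheno = synthetic.simulate_phenotypes(geno, small_cfg, np.random.default_rng(2))
        assert (pheno["necrosis_length_mm"] >= 0).all()
        assert (pheno["necrosis_length_mm"] <= pheno["shoot_length_mm"]).all()


class TestFixtures:
    def _make(self, tmpdir, seed):
        cfg = SimulationConfig(n_progeny=5, n_chromosomes=2,
                               markers_per_chromosome=3, qtl_marker_id=None,
                               random_seed=seed)
        rng = np.random.default_rng(seed)
        mm = synthetic.build_marker_map(cfg, rng)
        geno = synthetic.simulate_cross(mm, cfg, rng)
        obs = synthetic.simulate_observations(geno, cfg, rng)
        pheno = synthetic.simulate_phenotypes(geno, cfg, rng)
        return synthetic.write_fixtures(tmpdir, mm, geno, obs, pheno), (mm, obs, pheno)

    def test_same_seed_byte_identical(self, tmp_path):
        paths1, _ = self._make(tmp_path / "a", 7)
        paths2, _ = self._make(tmp_path / "b", 7)
        for key in paths1:
            assert paths1[key].read_bytes() == paths2[key].read_bytes()

    def test_round_trip(self, tmp_path):
        from gbsmap import io as gio

        paths, (mm, obs, pheno) = self._make(tmp_path, 7)
        mm2 = gio.read_marker_map_tsv(paths["markers"])
        pd.testing.assert_frame_equal(mm.table, mm2.table)
        obs2 = gio.read_observations_tsv(paths["observations"])
        pd.testing.assert_frame_equal(obs, obs2)
        pheno2 = gio.read_phenotypes_csv(paths["phenotypes"])
        pd.testing.assert_frame_equal(pheno, pheno2)

    def test_vcf_has_all_sample_columns(self, tmp_path):
        paths, _ = self._make(tmp_path, 7)
        header = [l for l in paths["truth_vcf"].read_text().splitlines()
                  if l.startswith("#CHROM")][0]
        samples = header.split("\t")[9:]
        assert len(samples) == 5 + 2  # progeny + both parents
        assert {"Idared", "Jackii"} <= set(samples)
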