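from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rohkit.genotype_io import HET, HOM_B
from rohkit.synthetic_data import (
    SimConfig,
    at_risk_records,
    autozygous_fraction,
    plant_disease_allele,
    plant_neutral_allele,
    simulate_founders,
    simulate_pedigree,
    truth_tract_lengths,
)


def small_config(**kw) -> SimConfig:
    base = dict(
        seed=101,
        n_autosomes=10,
        autosome_length=64_000_000,
        marker_spacing=500_000,  # sparse grid: truth geometry is marker-free
        x_length=None,
        n_offspring=150,
        error_rate=0.0,
        missing_rate=0.0,
    )
    base.update(kw)
    return SimConfig(**base)


class TestFounders:
    def test_mean_maf_matches_beta_expectation(self):
        cfg = small_config(beta_a=0.5, beta_b=0.5, marker_spacing=64_000, n_autosomes=1)
        pool = simulate_founders(cfg, n_haplotypes=400)
        maf = np.minimum(pool.freqs, 1 - pool.freqs)
        # E[min(p, 1-p)] for Beta(0.5, 0.5) by numerical quadrature
        grid = np.linspace(1e-6, 1 - 1e-6, 200_001)
        dens = grid ** (-0.5) * (1 - grid) ** (-0.5)
        expected = np.trapezoid(np.minimum(grid, 1 - grid) * dens, grid) / np.trapezoid(
            dens, grid
        )
        assert abs(maf.mean() - expected) < 0.02
        # realized allele frequencies follow the drawn marker frequencies
        realized = pool.alleles.mean(axis=0)
        assert abs((realized - pool.freqs).mean()) < 0.01

    def test_two_founder_pool_offspring_are_mosaics(self):
        cfg = small_config(pedigree="unrelated", n_offspring=20, marker_spacing=2_000_000)
        pool = simulate_founders(cfg, n_haplotypes=2)
        panel, _ = simulate_pedigree(cfg, pool)
        same = pool.alleles[0] == pool.alleles[1]
        expected_hom = (2 * pool.alleles[0][same]).astype(np.int8)
        for i in range(panel.n_samples):
            np.testing.assert_array_equal(panel.calls[i][same], expected_hom)

    def test_fixed_seed_reproduces_pool_and_panel(self):
        cfg = small_config(n_offspring=10, error_rate=0.01, missing_rate=0.01)
        pool1 = simulate_founders(cfg)
        pool2 = simulate_founders(cfg)
        np.testing.assert_array_equal(pool1.alleles, pool2.alleles)
        panel1, truth1 = simulate_pedigree(cfg, pool1)
        panel2, truth2 = simulate_pedigree(cfg, pool2)
        np.testing.assert_array_equal(panel1.calls, panel2.calls)
        pd.testing.assert_frame_equal(truth1, truth2)

    def test_markov_ld_increases_adjacent_concordance(self):
        flat = simulate_founders(small_config(n_autosomes=1, marker_spacing=64_000), 200)
        ld = simulate_founders(
            small_config(n_autosomes=1, marker_spacing=64_000, markov_r=0.8), 200
        )
        concord = lambda a: (a[:, 1:] == a[:, :-1]).mean()
        assert concord(ld.alleles) > concord(flat.alleles) + 0.05


class TestPedigrees:
    @pytest.mark.parametrize(
        "template,expected_f,tol",
        [("full_sib", 0.25, 0.02), ("first_cousin", 0.0625, 0.012)],
    )
    def test_mean_autozygous_fraction_matches_pedigree_f(self, template, expected_f, tol):
        cfg = small_config(pedigree=template)
        pool = simulate_founders(cfg)
        _, truth = simulate_pedigree(cfg, pool)
        assert abs(autozygous_fraction(truth).mean() - expected_f) < tol

    def test_unrelated_offspring_have_no_autozygosity(self):
        cfg = small_config(pedigree="unrelated", n_offspring=30)
        pool = simulate_founders(cfg)
        _, truth = simulate_pedigree(cfg, pool)
        assert not truth["autozygous"].any()

    def test_deeper_loops_give_shorter_tracts(self):
        """Loops through more distant ancestors shift tract lengths down."""
        shallow = small_config(pedigree="full_sib", seed=7)
        deep = small_config(pedigree="cousin:3", seed=7, n_offspring=400)
        l_sh = truth_tract_lengths(simulate_pedigree(shallow, simulate_founders(shallow))[1])
        l_dp = truth_tract_lengths(simulate_pedigree(deep, simulate_founders(deep))[1])
        assert len(l_dp) > 20
        for q in (0.25, 0.5, 0.75):
            assert np.quantile(l_dp, q) < np.quantile(l_sh, q)

    def test_truth_segments_tile_each_chromosome(self):
        cfg = small_config(n_offspring=10)
        pool = simulate_founders(cfg)
        _, truth = simulate_pedigree(cfg, pool)
        for (_, chrom), grp in truth.groupby(["sample", "chrom"]):
            grp = grp.sort_values("start")
            assert grp["start"].iloc[0] == 1
            assert grp["end"].iloc[-1] == cfg.autosome_length
            np.testing.assert_array_equal(
                grp["start"].iloc[1:].to_numpy(), grp["end"].iloc[:-1].to_numpy() + 1
            )

    def test_no_het_inside_truth_autozygous_segments_without_error(self):
        cfg = small_config(n_offspring=30, marker_spacing=100_000)
        pool = simulate_founders(cfg)
        panel, truth = simulate_pedigree(cfg, pool)
        mm = panel.markers
        for _, row in truth[truth["autozygous"]].iterrows():
            sl = mm.chrom_slice(row["chrom"])
            pos = mm.table["pos"].to_numpy()[sl]
            i0 = np.searchsorted(pos, row["start"], side="left")
            i1 = np.searchsorted(pos, row["end"], side="right")
            calls = panel.sample_calls(row["sample"])[sl][i0:i1]
            assert not (calls == HET).any()

    def test_error_model_perturbs_calls_but_not_truth(self):
        clean_cfg = small_config(n_offspring=20, marker_spacing=100_000)
        noisy_cfg = small_config(
            n_offspring=20, marker_spacing=100_000, error_rate=0.02, missing_rate=0.02
        )
        clean_panel, clean_truth = simulate_pedigree(clean_cfg, simulate_founders(clean_cfg))
        noisy_panel, noisy_truth = simulate_pedigree(noisy_cfg, simulate_founders(noisy_cfg))
        pd.testing.assert_frame_equal(clean_truth, noisy_truth)
        frac_changed = (clean_panel.calls != noisy_panel.calls).mean()
        assert 0.01 < frac_changed < 0.1


class TestDiseasePlanting:
    def cohort(self, carrier_freq, seed=31):
        cfg = small_config(
            seed=seed,
            n_autosomes=4,
            marker_spacing=200_000,
            n_offspring=100,
            pedigree_mixture={0: 0.3, 1: 0.7},
        )
        pool = simulate_founders(cfg)
        pos = pool.markers.positions("1")
        locus = ("1", int(pos[len(pos) // 2]))
        plant_disease_allele(pool, locus, carrier_freq, seed=seed + 1)
        panel, truth = simulate_pedigree(cfg, pool)
        return pool, panel, truth, locus

    def test_zero_carrier_freq_never_produces_at_risk(self):
        pool, panel, _, _ = self.cohort(0.0)
        assert at_risk_records(panel, pool).empty

    def test_second_origin_rejected(self):
        cfg = small_config(n_autosomes=2, marker_spacing=1_000_000, n_offspring=5)
        pool = simulate_founders(cfg)
        locus = ("1", int(pool.markers.positions("1")[3]))
        plant_disease_allele(pool, locus, 0.1, seed=1)
        with pytest.raises(ValueError, match="single origin"):
            plant_disease_allele(pool, locus, 0.1, seed=2)

    def test_incompatible_carrier_freq_rejected(self):
        cfg = small_config(n_autosomes=2, marker_spacing=1_000_000, n_offspring=5)
        pool = simulate_founders(cfg, n_haplotypes=10)
        locus = ("1", int(pool.markers.positions("1")[3]))
        with pytest.raises(ValueError, match="rounds to zero"):
            plant_disease_allele(pool, locus, 0.01, seed=1)

    def test_all_risk_homozygotes_covered_by_truth_autozygosity(self):
        """Single origin: every hom-risk dog is truth-autozygous at the locus."""
        pool, panel, truth, locus = self.cohort(0.3)
        records = at_risk_records(panel, pool)
        assert len(records) >= 3
        for _, rec in records.iterrows():
            seg = truth[
                (truth["sample"] == rec["sample"])
                & (truth["chrom"] == locus[0])
                & (truth["start"] <= locus[1])
                & (truth["end"] >= locus[1])
            ]
            assert len(seg) == 1 and bool(seg["autozygous"].iloc[0])

    def test_neutral_allele_has_independent_origins(self):
        cfg = small_config(n_autosomes=2, marker_spacing=1_000_000, n_offspring=5)
        pool = simulate_founders(cfg, n_haplotypes=200)
        midx = plant_neutral_allele(pool, 5, 0.25, seed=9)
        assert 0.15 < pool.alleles[:, midx].mean() < 0.35
        assert not pool.id_overrides and midx not in pool.planted
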