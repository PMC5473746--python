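"""Synthetic panel generators: determinism, filters, LD and mosaic structure."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import beavissim as bs
from beavissim.panels import GeneticMap, PanelConfig, export_vcf, import_vcf, make_shared_panels

from conftest import SMALL_ARMS


def _r2_by_distance(dosage, bp, pairs, rng):
    """Mean r^2 over random SNP pairs within each (lo, hi) bp-distance band."""
    out = []
    S = dosage.shape[1]
    for lo, hi in pairs:
        vals = []
        tries = 0
        while len(vals) < 200 and tries < 20_000:
            tries += 1
            i = int(rng.integers(0, S))
            d = np.abs(bp - bp[i])
            cand = np.flatnonzero((d >= lo) & (d <= hi))
            if cand.size == 0:
                continue
            j = int(rng.choice(cand))
            r = np.corrcoef(dosage[:, i], dosage[:, j])[0, 1]
            if np.isfinite(r):
                vals.append(r * r)
        out.append(np.mean(vals))
    return out


class TestGeneticMap:
    def test_linear_interpolation_round_trip(self):
        m = GeneticMap.linear("2L", 2_000_000, 2.5)
        bp = np.array([1, 500_000, 2_000_000])
        cm = m.bp_to_cm(bp)
        assert np.all(np.diff(cm) > 0)
        assert np.allclose(m.cm_to_bp(cm), bp)

    def test_rejects_unsorted_anchors(self):
        with pytest.raises(ValueError):
            GeneticMap("2L", np.array([10, 5]), np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            GeneticMap("2L", np.array([1, 10]), np.array([1.0, 0.0]))

    @given(st.lists(st.integers(1, 10**7), min_size=2, max_size=6, unique=True))
    @settings(deadline=None, max_examples=30)
    def test_interpolation_is_monotone(self, bps):
        m = GeneticMap.linear("X", 10**7, 2.0)
        cm = m.bp_to_cm(sorted(bps))
        assert np.all(np.diff(cm) >= 0)


class TestPanelConfig:
    def test_rejects_bad_dimensions(self):
        with pytest.raises(ValueError):
            PanelConfig(n_lines=1)
        with pytest.raises(ValueError):
            PanelConfig(n_snps=0)
        with pytest.raises(ValueError):
            PanelConfig(ambiguity_fraction=1.5)

    def test_missing_seed_rejected_at_generation(self):
        cfg = PanelConfig(n_lines=4, n_snps=10, arms=SMALL_ARMS)
        with pytest.raises(ValueError, match="seed"):
            bs.make_gwas_panel(cfg)


class TestGwasPanel:
    def test_same_seed_is_bit_identical(self):
        cfg = dict(n_lines=4, n_snps=10, arms=SMALL_ARMS)
        a = bs.make_gwas_panel(PanelConfig(seed=1, **cfg))
        b = bs.make_gwas_panel(PanelConfig(seed=1, **cfg))
        c = bs.make_gwas_panel(PanelConfig(seed=2, **cfg))
        assert np.array_equal(a.dosage, b.dosage)
        pd.testing.assert_frame_equal(a.snp_table, b.snp_table)
        assert not (a.n_snps == c.n_snps and np.array_equal(a.dosage, c.dosage))

    def test_dosages_inbred_and_maf_floor(self, gwas_small):
        assert set(np.unique(gwas_small.dosage)) <= {0, 2}
        assert gwas_small.maf.min() >= 0.025
        assert gwas_small.maf.max() <= 0.5
        tab = gwas_small.snp_table
        for arm in gwas_small.arm_names:
            bp = tab.loc[tab["arm"] == arm, "bp"].to_numpy()
            assert np.all(np.diff(bp) > 0)

    def test_maf_spectrum_enriched_toward_rare(self):
        cfg = PanelConfig(n_lines=200, n_snps=12_000, arms=SMALL_ARMS, seed=5)
        panel = bs.make_gwas_panel(cfg)
        counts, _ = np.histogram(panel.maf, bins=np.linspace(0.025, 0.5, 6))
        # monotone enrichment toward the floor, and a strong rejection of
        # a uniform frequency spectrum
        assert counts[0] > counts[-1] * 2
        from scipy.stats import chisquare

        assert chisquare(counts).pvalue < 1e-6

    def test_ld_decays_with_distance(self):
        cfg = PanelConfig(
            n_lines=200, n_snps=4_000, arms={"2L": 8_000_000},
            ld_scale_bp=100_000, seed=7,
        )
        panel = bs.make_gwas_panel(cfg)
        rng = np.random.default_rng(0)
        near, far = _r2_by_distance(
            panel.dosage.astype(float), panel.snp_table["bp"].to_numpy(),
            [(0, 50_000), (1_000_000, 8_000_000)], rng,
        )
        assert far <= near

    def test_serialization_round_trip(self, gwas_small, tmp_path):
        gwas_small.save(tmp_path / "p")
        back = bs.GwasPanel.load(tmp_path / "p")
        assert np.array_equal(back.dosage, gwas_small.dosage)
        assert np.array_equal(back.line_ids, gwas_small.line_ids)
        pd.testing.assert_frame_equal(back.snp_table, gwas_small.snp_table)


class TestMppPanel:
    def test_same_seed_is_bit_identical(self):
        cfg = dict(n_lines=5, n_snps=50, arms=SMALL_ARMS)
        a = bs.make_mpp_panel(PanelConfig(seed=3, **cfg))
        b = bs.make_mpp_panel(PanelConfig(seed=3, **cfg))
        assert np.array_equal(a.probs, b.probs)
        assert np.array_equal(a.founders, b.founders)

    def test_probability_rows_sum_to_one(self, mpp_small):
        mpp_small.check_probs(tol=1e-6)
        s = mpp_small.probs.sum(axis=2)
        assert np.abs(s - 1.0).max() < 1e-6

    def test_ambiguity_fraction_calibrated(self):
        cfg = PanelConfig(n_lines=150, n_snps=2_000, arms=SMALL_ARMS, seed=9,
                          ambiguity_fraction=0.04)
        panel = bs.make_mpp_panel(cfg)
        mx = panel.probs.max(axis=2)
        frac = np.mean((mx > 0.025) & (mx < 0.975))
        assert abs(frac - 0.04) < 0.01
        # and the Prob(REF) inferences show the same ambiguous share at
        # polymorphic SNPs
        probs = np.stack(
            [bs.impute_ref_prob(panel, j) for j in range(0, panel.n_snps, 7)]
        )
        interior = np.mean((probs > 0.025) & (probs < 0.975))
        assert 0.01 < interior < 0.10

    def test_no_recombination_gives_intact_founders(self):
        cfg = PanelConfig(
            n_lines=20, n_snps=100, arms=SMALL_ARMS, seed=4,
            breakpoint_rate_per_cm=0.0, ambiguity_fraction=0.0,
        )
        panel = bs.make_mpp_panel(cfg)
        for arm in panel.arm_names:
            gi = panel.grid_indices_for_arm(arm)
            f = panel.probs[:, gi, :].argmax(axis=2)
            assert np.all(f == f[:, :1])  # one founder per RIL per arm
        assert set(np.unique(panel.probs)) <= {0.0, 1.0}

    def test_founder_shares_near_one_eighth_without_drift(self):
        cfg = PanelConfig(
            n_lines=400, n_snps=200, arms=SMALL_ARMS, seed=6,
            founder_concentration=1e6,  # suppress drift
        )
        panel = bs.make_mpp_panel(cfg)
        freq = panel.probs.mean(axis=0)  # (positions, founders)
        assert np.allclose(freq.sum(axis=1), 1.0, atol=1e-6)
        se = np.sqrt(0.125 * 0.875 / 400)
        assert np.abs(freq.mean(axis=0) - 0.125).max() < 4 * se

    def test_founder_drift_disperses_shares(self):
        cfg = PanelConfig(n_lines=400, n_snps=200, arms=SMALL_ARMS, seed=6,
                          founder_concentration=4.0)
        panel = bs.make_mpp_panel(cfg)
        freq = panel.probs.mean(axis=0).mean(axis=0)
        assert np.allclose(freq.sum(), 1.0, atol=1e-6)
        assert freq.std() > 2 * np.sqrt(0.125 * 0.875 / 400)

    def test_wrong_founder_count_rejected_or_warned(self):
        cfg = PanelConfig(n_lines=5, n_snps=50, arms=SMALL_ARMS, seed=1, n_founders=4)
        with pytest.raises(ValueError, match="founders"):
            bs.make_mpp_panel(cfg)
        cfg2 = PanelConfig(n_lines=5, n_snps=50, arms=SMALL_ARMS, seed=1,
                           n_founders=4, strict_founders=False)
        with pytest.warns(UserWarning):
            panel = bs.make_mpp_panel(cfg2)
        assert panel.n_founders == 4

    def test_mpp_ld_longer_range_than_gwas(self):
        arms = {"2L": 6_000_000}
        gw = bs.make_gwas_panel(PanelConfig(n_lines=150, n_snps=1_200, arms=arms, seed=21))
        mp_ = bs.make_mpp_panel(PanelConfig(n_lines=150, n_snps=1_200, arms=arms, seed=22))
        rng = np.random.default_rng(1)
        # realized dosages for the MPP via binomial draws from Prob(REF)
        dos = np.stack(
            [bs.sample_genotypes(bs.impute_ref_prob(mp_, j), rng) for j in range(mp_.n_snps)],
            axis=1,
        )
        band = [(400_000, 1_000_000)]
        (mpp_mid,) = _r2_by_distance(dos.astype(float), mp_.snp_table["bp"].to_numpy(),
                                     band, rng)
        (gwas_mid,) = _r2_by_distance(gw.dosage.astype(float), gw.snp_table["bp"].to_numpy(),
                                      band, rng)
        assert mpp_mid > gwas_mid

    def test_serialization_round_trip(self, mpp_small, tmp_path):
        mpp_small.save(tmp_path / "m")
        back = bs.MppPanel.load(tmp_path / "m")
        assert np.array_equal(back.probs, mpp_small.probs)
        assert np.array_equal(back.founders, mpp_small.founders)
        pd.testing.assert_frame_equal(back.grid, mpp_small.grid)


class TestSharedPanels:
    def test_shared_snps_have_matching_coordinates(self):
        arms = {"2L": 3_000_000, "2R": 3_000_000}
        cg = PanelConfig(n_lines=60, n_snps=3_000, arms=arms)
        cm = PanelConfig(n_lines=60, n_snps=1_500, arms=arms)
        gw, mp_ = make_shared_panels(cg, cm, seed=31)
        key = lambda t: set(zip(t["arm"], t["bp"]))
        shared = key(gw.snp_table) & key(mp_.snp_table)
        assert len(shared) > 100
        # shared sites have correlated but unequal frequencies
        gt = gw.snp_table.set_index(["arm", "bp"]).loc[sorted(shared), "maf"]
        mt = mp_.snp_table.set_index(["arm", "bp"]).loc[sorted(shared), "maf"]
        r = np.corrcoef(gt.to_numpy(), mt.to_numpy())[0, 1]
        assert 0.05 < r < 0.999

    def test_mismatched_arms_rejected(self):
        cg = PanelConfig(n_lines=10, n_snps=100, arms={"2L": 3_000_000})
        cm = PanelConfig(n_lines=10, n_snps=100, arms={"3L": 3_000_000})
        with pytest.raises(ValueError, match="arm"):
            make_shared_panels(cg, cm, seed=1)


class TestVcfAdapter:
    def test_round_trip(self, tmp_path):
        cfg = PanelConfig(n_lines=8, n_snps=60, arms={"2L": 3_000_000}, seed=13)
        panel = bs.make_gwas_panel(cfg)
        path = tmp_path / "panel.vcf"
        export_vcf(panel, path)
        back = import_vcf(path)
        assert np.array_equal(back.dosage, panel.dosage)
        assert np.array_equal(back.snp_table["bp"].to_numpy(),
                              panel.snp_table["bp"].to_numpy())

    def test_heterozygote_policy(self, tmp_path):
        path = tmp_path / "het.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=2L,length=1000000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\n"
            "2L\t100\t.\tA\tC\t.\t.\t.\tGT\t0/0\t1/1\n"
            "2L\t200\t.\tG\tT\t.\t.\t.\tGT\t0/1\t1/1\n"
        )
        with pytest.raises(ValueError, match="heterozygous"):
            import_vcf(path, on_het="error")
        panel = import_vcf(path, on_het="drop")
        assert panel.n_snps == 1 and panel.snp_table["bp"].iloc[0] == 100
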