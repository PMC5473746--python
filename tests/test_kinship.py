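"""Imputation, MAF filtering, GRM/IBD kinship and relatedness pruning."""

import numpy as np
import pytest

import beavissim as bs
from beavissim.kinship import (
    KinshipMatrix,
    OutsideGridError,
    ref_prob_at,
    _grm_parts,
)
from beavissim.mapping import MappingContext, fit_null

from conftest import toy_gwas_panel, toy_mpp_panel, identity_kinships


def _uniform_probs(n, m, k=8):
    return np.full((n, m, k), 1.0 / k, dtype=np.float32)


def _certain_probs(founder_idx):
    """One-hot tensor from an (n, m) array of true founder indices."""
    f = np.asarray(founder_idx)
    n, m = f.shape
    P = np.zeros((n, m, 8), dtype=np.float32)
    P[np.arange(n)[:, None], np.arange(m)[None, :], f] = 1.0
    return P


class TestImputeRefProb:
    def test_all_founders_reference(self):
        panel = toy_mpp_panel(_uniform_probs(3, 4), np.ones((8, 4)))
        assert np.allclose(bs.impute_ref_prob(panel, 0), 1.0)

    def test_uniform_probabilities_average_founders(self):
        F = np.zeros((8, 1))
        F[:2, 0] = 1  # two of eight founders carry the reference allele
        panel = toy_mpp_panel(_uniform_probs(3, 1), F)
        assert np.allclose(bs.impute_ref_prob(panel, 0), 0.25)

    def test_certain_founder(self):
        P = _certain_probs(np.zeros((2, 1), dtype=int))
        F = np.zeros((8, 1))
        F[0, 0] = 1
        panel = toy_mpp_panel(P, F)
        assert np.allclose(bs.impute_ref_prob(panel, 0), 1.0)

    def test_convex_combination_of_founder_alleles(self, mpp_small):
        for j in (0, 5, 17):
            p = bs.impute_ref_prob(mpp_small, j)
            assert p.min() >= 0.0 and p.max() <= 1.0

    def test_outside_grid_span_rejected(self):
        panel = toy_mpp_panel(_uniform_probs(2, 3), np.ones((8, 3)))
        with pytest.raises(OutsideGridError):
            ref_prob_at(panel, "2L", 10**9, np.ones(8))
        with pytest.raises(OutsideGridError):
            ref_prob_at(panel, "2L", 1, np.ones(8))


class TestSampleGenotypes:
    def test_degenerate_probabilities(self):
        assert np.all(bs.sample_genotypes(np.ones(50), 1) == 2)
        assert np.all(bs.sample_genotypes(np.zeros(50), 1) == 0)

    def test_half_probability_matches_binomial(self):
        dos = bs.sample_genotypes(np.full(100_000, 0.5), 3)
        f = (dos == 2).mean()
        assert abs(f - 0.5) < 3 * np.sqrt(0.25 / 100_000)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            bs.sample_genotypes(np.array([0.5, 1.2]), 1)

    def test_per_line_frequency_tracks_prob_ref(self):
        probs = np.array([0.1, 0.5, 0.9])
        draws = np.stack([bs.sample_genotypes(probs, s) for s in range(2000)])
        freq = (draws == 2).mean(axis=0)
        assert np.abs(freq - probs).max() < 3 * np.sqrt(0.25 / 2000)


class TestMafFilter:
    @pytest.mark.parametrize(
        "ref_copies,floor,kept",
        [(3, 0.025, True), (2, 0.025, False), (0, 0.025, False)],
    )
    def test_copy_count_thresholds(self, ref_copies, floor, kept):
        dos = np.zeros((100, 1), dtype=np.int8)
        dos[:ref_copies, 0] = 2
        if not kept and ref_copies == 0:
            with pytest.raises(ValueError):
                bs.maf_filter(dos, floor)
            return
        mask = (
            bs.maf_filter(np.column_stack([dos, np.full((100, 1), 2, np.int8),
                                           np.tile([0, 2], 50)[:, None]]), floor)
        )
        assert mask[0] == kept
        assert not mask[1]  # monomorphic always dropped
        assert mask[2]

    def test_alternative_floor(self):
        maf = np.array([0.03, 0.06])
        assert bs.maf_filter(maf, 0.05).tolist() == [False, True]


class TestGrm:
    def test_identical_lines_match_diagonal(self):
        dos = np.tile(np.array([[0, 2, 2, 0, 2], [0, 2, 2, 0, 2], [2, 0, 2, 2, 0]],
                               dtype=np.int8), (1, 20))
        K = bs.grm(dos).K
        assert np.isclose(K[0, 1], K[0, 0])
        assert K[0, 2] < K[0, 0]

    def test_independent_lines_mean_off_diagonal_near_zero(self):
        rng = np.random.default_rng(0)
        dos = 2 * (rng.random((40, 5_000)) < 0.3).astype(np.int8)
        K = bs.grm(dos).K
        off = K[np.triu_indices(40, 1)]
        # column centering makes the expected off-diagonal -diag/(n-1),
        # which tends to zero as the panel grows
        assert abs(off.mean() + 1.0 / 39.0) < 0.01
        assert abs(np.diag(K).mean() - 1.0) < 0.1

    def test_deterministic_and_symmetric(self, gwas_small):
        K1 = bs.grm(gwas_small).K
        K2 = bs.grm(gwas_small).K
        assert np.array_equal(K1, K2)
        assert np.allclose(K1, K1.T, atol=1e-12)

    def test_invariant_to_allele_label_swap(self, gwas_small):
        K1 = bs.grm(gwas_small).K
        flipped = gwas_small.dosage.copy()
        flipped[:, ::3] = 2 - flipped[:, ::3]  # swap ref/alt at every third SNP
        K2 = bs.grm(flipped, gwas_small.line_ids).K
        assert np.allclose(K1, K2, atol=1e-10)

    def test_all_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            bs.grm(np.full((5, 10), 2, dtype=np.int8))


class TestIbdKinship:
    def test_self_kinship_one_when_certain(self):
        P = _certain_probs(np.array([[0, 1, 2], [3, 3, 3]]))
        panel = toy_mpp_panel(P, np.ones((8, 3)))
        K = bs.ibd_kinship(panel).K
        assert np.allclose(np.diag(K), 1.0)

    def test_disjoint_founders_zero(self):
        P = _certain_probs(np.array([[0, 0, 0], [1, 1, 1]]))
        panel = toy_mpp_panel(P, np.ones((8, 3)))
        assert np.isclose(bs.ibd_kinship(panel).K[0, 1], 0.0)

    def test_uniform_probabilities_give_one_eighth(self):
        panel = toy_mpp_panel(_uniform_probs(2, 4), np.ones((8, 4)))
        K = bs.ibd_kinship(panel).K
        assert np.allclose(K, 1.0 / 8.0)

    def test_self_kinship_below_one_with_ambiguity(self, mpp_small):
        K = bs.ibd_kinship(mpp_small).K
        assert np.all(np.diag(K) <= 1.0 + 1e-6)
        assert np.all(K >= -1e-6) and np.all(K <= 1.0 + 1e-6)


class TestLoco:
    def test_excluded_arm_recomputation_oracle(self, gwas_small):
        loco = bs.loco_kinships(gwas_small)
        other = gwas_small.snp_indices_for_arm("2R")
        G, c = _grm_parts(gwas_small.dosage[:, other])
        assert np.allclose(loco["2L"].K, G / c, atol=1e-12)

    def test_identical_arm_content_gives_equal_matrices(self):
        block = 2 * (np.random.default_rng(3).random((20, 50)) < 0.4).astype(np.int8)
        panel = toy_gwas_panel(np.hstack([block, block]))
        tab = panel.snp_table
        tab.loc[tab.index[50:], "arm"] = "2R"
        from beavissim.panels import GeneticMap

        panel.maps["2R"] = GeneticMap.linear("2R", 200_000, 2.5)
        loco = bs.loco_kinships(panel)
        assert np.allclose(loco["2L"].K, loco["2R"].K, atol=1e-12)

    def test_loco_differs_from_global(self, gwas_small):
        loco = bs.loco_kinships(gwas_small)
        K_global = bs.grm(gwas_small).K
        assert not np.allclose(loco["2L"].K, K_global, atol=1e-8)

    def test_single_arm_rejected(self):
        panel = toy_gwas_panel(np.array([[0, 2], [2, 0], [0, 0]], dtype=np.int8))
        with pytest.raises(ValueError, match="two chromosome arms"):
            bs.loco_kinships(panel)

    def test_mpp_loco_matches_manual_recomputation(self, mpp_small):
        loco = bs.loco_kinships(mpp_small)
        gi = mpp_small.grid_indices_for_arm("2R")
        P = mpp_small.probs[:, gi, :].astype(np.float64)
        n, m, k = P.shape
        M = P.reshape(n, m * k)
        assert np.allclose(loco["2L"].K, (M @ M.T) / m, atol=1e-5)


class TestDropRelated:
    def _panel(self, n=3):
        return toy_gwas_panel(2 * np.eye(n, 6, dtype=np.int8))

    def test_unrelated_panel_unchanged(self):
        panel = self._panel()
        K = KinshipMatrix(panel.line_ids, np.eye(3), "global", "grm")
        reduced, dropped = bs.drop_related(panel, K=K)
        assert dropped == [] and reduced.n_lines == 3

    def test_duplicated_line_drops_exactly_one(self):
        rng = np.random.default_rng(1)
        dos = 2 * (rng.random((5, 400)) < 0.4).astype(np.int8)
        dos[1] = dos[0]
        panel = toy_gwas_panel(dos)
        reduced, dropped = bs.drop_related(panel)
        assert len(dropped) == 1 and dropped[0] in ("L0", "L1")

    def test_chain_drops_middle_line(self):
        # A~B and B~C exceed the threshold, A~C does not: removing B (the
        # highest-degree line, the brute-force minimal vertex cover) suffices
        K = np.array([[1.0, 0.5, 0.1], [0.5, 1.0, 0.5], [0.1, 0.5, 1.0]])
        panel = self._panel()
        Km = KinshipMatrix(panel.line_ids, K, "global", "grm")
        reduced, dropped = bs.drop_related(panel, K=Km)
        assert dropped == ["L1"]
        assert list(reduced.line_ids) == ["L0", "L2"]

    def test_tie_breaks_to_later_id(self):
        K = np.array([[1.0, 0.6], [0.6, 1.0]])
        panel = self._panel(2)
        Km = KinshipMatrix(panel.line_ids, K, "global", "grm")
        _, dropped = bs.drop_related(panel, K=Km)
        assert dropped == ["L1"]


class TestLocoConservativeness:
    def test_loco_lod_at_causative_not_depressed_vs_global(self):
        """Including the causative arm in the kinship depresses the signal;
        the LOCO scan does not (mean causative-SNP LOD is at least as high)."""
        cfg = bs.PanelConfig(n_lines=80, n_snps=2_000,
                             arms={"2L": 2_000_000, "2R": 2_000_000}, seed=44)
        panel = bs.make_gwas_panel(cfg)
        loco = bs.loco_kinships(panel)
        K_global = bs.grm(panel)
        globals_ = {arm: K_global for arm in panel.arm_names}
        ctx_loco = MappingContext(panel, kinships=loco)
        ctx_glob = MappingContext(panel, kinships=globals_)
        rng = np.random.default_rng(7)
        diffs = []
        for r in range(200):
            snp = int(rng.integers(0, panel.n_snps))
            ph = bs.simulate_biallelic(panel, snp, 0.15, r)
            arm, c = ctx_loco.center_for_snp(snp)
            lod_l = ctx_loco.scan_region(ph.y, arm, c, halfwidth_bp=1).peak_lod
            lod_g = ctx_glob.scan_region(ph.y, arm, c, halfwidth_bp=1).peak_lod
            diffs.append(lod_l - lod_g)
        assert np.mean(diffs) >= 0.0


def test_kinship_matrix_written_as_square_tsv(tmp_path):
    ids = np.array(["a", "b"])
    K = KinshipMatrix(ids, np.array([[1.0, 0.25], [0.25, 1.0]]), "global", "grm")
    K.write_tsv(tmp_path / "k.tsv")
    lines = (tmp_path / "k.tsv").read_text().strip().split("\n")
    assert lines[0].split("\t") == ["a", "b"]
    assert [float(v) for v in lines[1].split("\t")] == [1.0, 0.25]
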