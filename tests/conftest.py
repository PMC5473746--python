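import numpy as np
import pandas as pd
import pytest

import beavissim as bs
from beavissim.panels import GeneticMap, GwasPanel, MppPanel

SMALL_ARMS = {"2L": 3_000_000, "2R": 3_000_000}


@pytest.fixture(scope="session")
def gwas_small():
    """60 inbred lines, two 3 Mb arms, ~2.5k SNPs."""
    cfg = bs.PanelConfig(n_lines=60, n_snps=3_000, arms=SMALL_ARMS, seed=11)
    return bs.make_gwas_panel(cfg)


@pytest.fixture(scope="session")
def mpp_small():
    """60 RILs, two 3 Mb arms, 10 kb grid."""
    cfg = bs.PanelConfig(n_lines=60, n_snps=3_000, arms=SMALL_ARMS, seed=12)
    return bs.make_mpp_panel(cfg)


def identity_kinships(panel):
    """LOCO set of identity matrices (reduces the mixed model to OLS)."""
    from beavissim.kinship import KinshipMatrix

    I = np.eye(panel.n_lines)
    return {
        arm: KinshipMatrix(panel.line_ids, I, f"loco:{arm}", "grm")
        for arm in panel.arm_names
    }


def toy_mpp_panel(probs, founders, grid_bp=None, arm="2L", snp_bp=None):
    """Hand-built MPP panel from an explicit probability tensor.

    ``probs``: (n_rils, n_grid, n_founders); ``founders``: (n_founders,
    n_snps) reference-allele indicators.  SNPs sit on the grid positions by
    default.
    """
    probs = np.asarray(probs, dtype=np.float32)
    founders = np.asarray(founders, dtype=np.uint8)
    n, m, k = probs.shape
    if grid_bp is None:
        grid_bp = np.arange(1, m + 1) * 10_000
    grid_bp = np.asarray(grid_bp)
    length = int(grid_bp[-1] + 10_000)
    gmap = GeneticMap.linear(arm, length, 2.5)
    grid = pd.DataFrame({"arm": arm, "bp": grid_bp, "cM": gmap.bp_to_cm(grid_bp)})
    S = founders.shape[1]
    if snp_bp is None:
        snp_bp = grid_bp[np.arange(S) % m]
    gi = np.array([int(np.argmin(np.abs(grid_bp - b))) for b in snp_bp])
    snp_table = pd.DataFrame(
        {
            "arm": arm,
            "bp": snp_bp,
            "cM": gmap.bp_to_cm(snp_bp),
            "ref": "A",
            "alt": "C",
            "maf": 0.25,
            "grid_index": gi,
        }
    )
    return MppPanel(
        line_ids=np.array([f"RIL{i}" for i in range(n)]),
        founders=founders,
        probs=probs,
        grid=grid,
        snp_table=snp_table,
        maps={arm: gmap},
    )


def toy_gwas_panel(dosage, arm="2L", bp=None, maps=None):
    """Hand-built GWAS panel from an explicit dosage matrix."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, S = dosage.shape
    if bp is None:
        bp = np.arange(1, S + 1) * 1_000
    bp = np.asarray(bp)
    if maps is None:
        maps = {arm: GeneticMap.linear(arm, int(bp[-1] + 1_000), 2.5)}
    f = dosage.mean(axis=0) / 2.0
    snp_table = pd.DataFrame(
        {
            "arm": arm,
            "bp": bp,
            "cM": maps[arm].bp_to_cm(bp),
            "ref": "A",
            "alt": "C",
            "maf": np.minimum(f, 1 - f),
        }
    )
    return GwasPanel(
        line_ids=np.array([f"L{i}" for i in range(n)]),
        snp_table=snp_table,
        dosage=dosage,
        maps=maps,
    )
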