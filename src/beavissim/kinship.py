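"""Genotype imputation, frequency filters and kinship matrices.

For the GWAS design, kinship is a VanRaden-style genomic relationship matrix
(GRM) from column-centered dosages.  For the multiparent design, kinship is
the expected proportion of the genome identical by descent (IBD), computed
directly from the founder-probability tensor.  Both come in a global flavor
and a leave-one-chromosome-out (LOCO) set: when a marker on arm A is tested,
the kinship matrix that excludes arm A's markers is used, which avoids the
over-conservative behavior of including the tested locus in the relatedness
correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panels import GwasPanel, MppPanel
from ._rng import rng_for

__all__ = [
    "KinshipMatrix",
    "OutsideGridError",
    "impute_ref_prob",
    "ref_prob_at",
    "sample_genotypes",
    "compute_maf",
    "maf_filter",
    "grm",
    "ibd_kinship",
    "loco_kinships",
    "drop_related",
]


class OutsideGridError(ValueError):
    """Requested position lies outside the genotyped grid span."""


@dataclass
class KinshipMatrix:
    line_ids: np.ndarray
    K: np.ndarray
    scope: str  # "global" or "loco:<arm>"
    method: str  # "grm" or "ibd"

    def __post_init__(self):
        if self.K.shape[0] != self.K.shape[1] or self.K.shape[0] != len(self.line_ids):
            raise ValueError("kinship matrix must be square over line_ids")
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")

    def write_tsv(self, path) -> None:
        ids = list(map(str, self.line_ids))
        with open(path, "w") as fh:
            fh.write("\t".join(ids) + "\n")
            for row in self.K:
                fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# founder-probability genotype imputation
# ---------------------------------------------------------------------------

def impute_ref_prob(panel: MppPanel, snp_index: int) -> np.ndarray:
    """Per-RIL probability of carrying the reference allele at a SNP.

    Prob(REF) = sum_i F_i * P_i over the 8 founders, with founder
    probabilities taken at the genotyped grid position nearest the SNP.
    """
    row = panel.snp_table.iloc[int(snp_index)]
    g = int(row["grid_index"])
    F = panel.founders[:, int(snp_index)].astype(np.float64)
    return panel.probs[:, g, :].astype(np.float64) @ F


def ref_prob_at(panel: MppPanel, arm: str, bp: float, founder_ref: np.ndarray) -> np.ndarray:
    """Prob(REF) at an arbitrary (arm, bp) given founder reference alleles.

    Raises :class:`OutsideGridError` when the position lies outside the
    genotyped span of the arm.
    """
    idx = panel.grid_indices_for_arm(arm)
    if idx.size == 0:
        raise OutsideGridError(f"arm {arm!r} has no genotyped positions")
    pos = panel.grid["bp"].to_numpy()[idx]
    if bp < pos[0] or bp > pos[-1]:
        raise OutsideGridError(
            f"{arm}:{bp} outside genotyped span [{pos[0]}, {pos[-1]}]"
        )
    g = int(idx[np.argmin(np.abs(pos - bp))])
    F = np.asarray(founder_ref, dtype=np.float64)
    if F.shape != (panel.n_founders,):
        raise ValueError("founder_ref must have one entry per founder")
    return panel.probs[:, g, :].astype(np.float64) @ F


def sample_genotypes(probs: np.ndarray, seed) -> np.ndarray:
    """One Bernoulli draw per line from Prob(REF); dosage coded {0, 2}."""
    probs = np.asarray(probs, dtype=float)
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else rng_for(seed, "genotypes")
    return (2 * (rng.random(probs.shape) < probs)).astype(np.int8)


# ---------------------------------------------------------------------------
# frequency filters
# ---------------------------------------------------------------------------

def compute_maf(dosage: np.ndarray) -> np.ndarray:
    f = np.asarray(dosage, dtype=float).mean(axis=0) / 2.0
    return np.minimum(f, 1.0 - f)


def maf_filter(maf_or_dosage: np.ndarray, floor: float = 0.025) -> np.ndarray:
    """Boolean mask of SNPs whose minor-allele frequency is >= ``floor``.

    Accepts either a MAF vector or a dosage matrix.  Monomorphic SNPs
    (MAF 0) never pass.  Raises if nothing survives.
    """
    arr = np.asarray(maf_or_dosage)
    maf = compute_maf(arr) if arr.ndim == 2 else arr.astype(float)
    keep = maf >= floor
    if not keep.any():
        raise ValueError(f"no SNPs pass the MAF floor {floor}")
    return keep


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

def _grm_parts(dosage: np.ndarray) -> tuple[np.ndarray, float]:
    """Cross-product and normalizer for a dosage block ({0,2} coding).

    Zero-variance columns contribute nothing to either term.
    """
    D = np.asarray(dosage, dtype=np.float64)
    p = D.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    Z = D[:, poly] - 2.0 * p[poly][None, :]
    c = float(4.0 * np.sum(p[poly] * (1.0 - p[poly])))
    return Z @ Z.T, c


def grm(panel: GwasPanel | np.ndarray, line_ids: np.ndarray | None = None) -> KinshipMatrix:
    """VanRaden genomic relationship matrix from centered {0,2} dosages.

    K = Z Z' / (4 sum p(1-p)); with this normalizer the diagonal averages
    ~1 for unrelated inbred lines.  Any fixed positive rescaling would be
    absorbed by the variance components downstream.
    """
    if isinstance(panel, GwasPanel):
        dosage, line_ids = panel.dosage, panel.line_ids
    else:
        dosage = panel
        if line_ids is None:
            line_ids = np.array([f"L{i:04d}" for i in range(dosage.shape[0])])
    G, c = _grm_parts(dosage)
    if c <= 0:
        raise ValueError("all SNPs are monomorphic; GRM undefined")
    return KinshipMatrix(line_ids, G / c, "global", "grm")


def ibd_kinship(panel: MppPanel, n_positions: int | None = None) -> KinshipMatrix:
    """Pairwise expected proportion of the genome identical by descent.

    K[a, b] = (1/n) sum_j sum_i F_{i,j,a} F_{i,j,b} over founder
    probabilities at ``n_positions`` grid positions evenly spaced on the
    genetic map (all grid positions by default).  Entries lie in [0, 1];
    the diagonal equals 1 exactly where probabilities are certain.
    """
    idx = _even_cm_positions(panel, n_positions)
    G, m = _ibd_parts(panel, idx)
    return KinshipMatrix(panel.line_ids, G / m, "global", "ibd")


def _even_cm_positions(panel: MppPanel, n_positions: int | None) -> np.ndarray:
    if n_positions is None or n_positions >= len(panel.grid):
        return np.arange(len(panel.grid))
    cm = panel.grid["cM"].to_numpy()
    # cumulative genetic position across arms for even spacing on the cM scale
    arms = panel.grid["arm"].to_numpy()
    offs = np.zeros(len(cm))
    total = 0.0
    for arm in panel.arm_names:
        sel = arms == arm
        offs[sel] = total
        total += cm[sel].max() if sel.any() else 0.0
    gcm = cm + offs
    targets = np.linspace(gcm[0], gcm[-1], n_positions)
    return np.unique(np.searchsorted(gcm, targets).clip(0, len(gcm) - 1))


def _ibd_parts(panel: MppPanel, idx: np.ndarray) -> tuple[np.ndarray, int]:
    P = panel.probs[:, idx, :]
    n, m, k = P.shape
    M = np.ascontiguousarray(P.reshape(n, m * k), dtype=np.float32)
    return (M @ M.T).astype(np.float64), m


def loco_kinships(
    panel: GwasPanel | MppPanel, method: str | None = None, n_positions: int | None = None
) -> dict[str, KinshipMatrix]:
    """One kinship matrix per arm, each built from all *other* arms' markers."""
    arms = panel.arm_names
    if len(arms) < 2:
        raise ValueError("LOCO kinship requires at least two chromosome arms")
    if method is None:
        method = "grm" if isinstance(panel, GwasPanel) else "ibd"

    out: dict[str, KinshipMatrix] = {}
    if method == "grm":
        parts = {}
        for arm in arms:
            cols = panel.snp_indices_for_arm(arm)
            parts[arm] = _grm_parts(panel.dosage[:, cols])
        for arm in arms:
            G = sum(parts[a][0] for a in arms if a != arm)
            c = sum(parts[a][1] for a in arms if a != arm)
            if c <= 0:
                raise ValueError(f"no polymorphic markers outside arm {arm}")
            out[arm] = KinshipMatrix(panel.line_ids, G / c, f"loco:{arm}", "grm")
    elif method == "ibd":
        idx = _even_cm_positions(panel, n_positions)
        arm_of = panel.grid["arm"].to_numpy()[idx]
        parts = {}
        for arm in arms:
            sub = idx[arm_of == arm]
            parts[arm] = _ibd_parts(panel, sub) if sub.size else (0.0, 0)
        for arm in arms:
            G = sum(parts[a][0] for a in arms if a != arm)
            m = sum(parts[a][1] for a in arms if a != arm)
            if m == 0:
                raise ValueError(f"no kinship positions outside arm {arm}")
            out[arm] = KinshipMatrix(panel.line_ids, G / m, f"loco:{arm}", "ibd")
    else:
        raise ValueError("method must be 'grm' or 'ibd'")
    return out


# ---------------------------------------------------------------------------
# relatedness pruning
# ---------------------------------------------------------------------------

def drop_related(
    panel: GwasPanel,
    threshold: float = 0.25,
    K: KinshipMatrix | None = None,
) -> tuple[GwasPanel, list[str]]:
    """Greedily drop lines until no pair's coancestry exceeds ``threshold``.

    At each step the line involved in the most over-threshold pairs is
    removed; among ties the lexicographically later line id is dropped, so
    the result is reproducible.
    """
    if K is None:
        K = grm(panel)
    A = K.K.copy()
    np.fill_diagonal(A, 0.0)
    ids = list(map(str, panel.line_ids))
    alive = np.ones(len(ids), dtype=bool)
    dropped: list[str] = []
    while True:
        over = (A > threshold) & alive[:, None] & alive[None, :]
        deg = over.sum(axis=1)
        if deg.max(initial=0) == 0:
            break
        top = np.flatnonzero(deg == deg.max())
        victim = max(top, key=lambda i: ids[i])
        alive[victim] = False
        dropped.append(ids[victim])
    return panel.subset_lines(np.flatnonzero(alive)), dropped
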