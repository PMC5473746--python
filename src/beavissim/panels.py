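"""Synthetic mapping panels.

Two panel designs are generated with the statistical structure that the
downstream mapping pipeline assumes:

* :class:`GwasPanel` — a collection of fully inbred, resequenced lines from a
  natural population.  Biallelic SNP dosages are coded ``{0, 2}`` (haploid
  lines scored as homozygous diploids), the minor-allele-frequency spectrum is
  skewed toward rare variants (density proportional to 1/q, truncated at a
  configurable floor), linkage disequilibrium is short-range, and background
  relatedness arises from a finite pool of ancestral haplotypes that lines
  copy along each chromosome arm.

* :class:`MppPanel` — a multiparent panel: 8 fully genotyped founder strains
  and recombinant inbred lines (RILs) that are mosaics of founder segments.
  Each RIL carries per-position probability vectors over the 8 founders on a
  regular genotyping grid; probabilities are nearly certain, with a small
  configurable fraction of ambiguous positions, emulating the output of a
  haplotype-inference HMM.

Both generators are fully determined by a single integer seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import rng_for

__all__ = [
    "GeneticMap",
    "PanelConfig",
    "GwasPanel",
    "MppPanel",
    "make_gwas_panel",
    "make_mpp_panel",
    "make_shared_panels",
    "make_gene_catalog",
    "export_vcf",
    "import_vcf",
]

#: Default genome: five major chromosome arms, lengths in bp.
DEFAULT_ARMS: dict[str, int] = {
    "X": 22_000_000,
    "2L": 22_000_000,
    "2R": 22_000_000,
    "3L": 22_000_000,
    "3R": 22_000_000,
}

_NUC = np.array(list("ACGT"))


@dataclass(frozen=True)
class GeneticMap:
    """Piecewise-linear physical <-> genetic map for one chromosome arm.

    Coordinates are 1-based inclusive bp; cM is non-decreasing in bp.
    """

    arm: str
    anchors_bp: np.ndarray
    anchors_cm: np.ndarray

    def __post_init__(self):
        bp = np.asarray(self.anchors_bp, dtype=np.int64)
        cm = np.asarray(self.anchors_cm, dtype=float)
        if bp.ndim != 1 or bp.shape != cm.shape or bp.size < 2:
            raise ValueError("map needs matching 1-d anchor arrays of length >= 2")
        if not np.all(np.diff(bp) > 0):
            raise ValueError("anchor bp must be strictly increasing")
        if not np.all(np.diff(cm) >= 0):
            raise ValueError("anchor cM must be non-decreasing")
        object.__setattr__(self, "anchors_bp", bp)
        object.__setattr__(self, "anchors_cm", cm)

    @classmethod
    def linear(cls, arm: str, length_bp: int, cm_per_mb: float) -> "GeneticMap":
        return cls(arm, np.array([1, length_bp]), np.array([0.0, (length_bp - 1) * cm_per_mb / 1e6]))

    @property
    def length_bp(self) -> int:
        return int(self.anchors_bp[-1])

    def bp_to_cm(self, bp) -> np.ndarray:
        return np.interp(np.asarray(bp, dtype=float), self.anchors_bp, self.anchors_cm)

    def cm_to_bp(self, cm) -> np.ndarray:
        return np.interp(np.asarray(cm, dtype=float), self.anchors_cm, self.anchors_bp)


@dataclass
class PanelConfig:
    """Parameters shared by both panel generators.

    The defaults are the study conditions used throughout: a five-arm,
    110 Mb genome at 2.5 cM/Mb (~275 cM), MAF floor 2.5%, and — for the
    multiparent design — 8 founders, a 10 kb genotyping grid, near-certain
    founder probabilities with 4% ambiguous positions, and Poisson
    breakpoints at 0.2 per cM (mean intact segment ~2 Mb, so imputed-SNP LD
    decays to background within roughly 2 Mb).
    """

    n_lines: int = 100
    n_snps: int = 10_000
    arms: dict[str, int] | None = None
    cm_per_mb: float = 2.5
    maf_floor: float = 0.025
    spectrum_qmin: float = 0.025
    spectrum_qmax: float = 0.5
    # GWAS design
    ld_scale_bp: float = 500.0
    haplotype_pool_size: int = 32
    pool_concentration: float = 2.0
    # MPP design
    n_founders: int = 8
    breakpoint_rate_per_cm: float = 0.2
    founder_concentration: float = 4.0
    ambiguity_fraction: float = 0.04
    grid_spacing_bp: int = 10_000
    strict_founders: bool = True
    seed: int | None = None

    def __post_init__(self):
        if self.arms is None:
            self.arms = dict(DEFAULT_ARMS)
        if self.n_lines < 2:
            raise ValueError("n_lines must be >= 2")
        if self.n_snps < 1:
            raise ValueError("n_snps must be positive")
        if not (0.0 <= self.ambiguity_fraction <= 1.0):
            raise ValueError("ambiguity_fraction must lie in [0, 1]")
        if self.breakpoint_rate_per_cm < 0:
            raise ValueError("breakpoint rate must be >= 0")
        if any(l <= self.grid_spacing_bp for l in self.arms.values()):
            raise ValueError("arm lengths must exceed the grid spacing")

    def maps(self) -> dict[str, GeneticMap]:
        return {a: GeneticMap.linear(a, l, self.cm_per_mb) for a, l in self.arms.items()}

    def require_seed(self) -> int:
        if self.seed is None:
            raise ValueError("PanelConfig.seed must be set for reproducible generation")
        return int(self.seed)


def _allocate(total: int, weights: np.ndarray) -> np.ndarray:
    """Split ``total`` proportionally to ``weights`` (largest remainder)."""
    raw = total * weights / weights.sum()
    out = np.floor(raw).astype(int)
    rem = total - out.sum()
    order = np.argsort(raw - out)[::-1]
    out[order[:rem]] += 1
    return out


def _draw_spectrum(rng: np.random.Generator, size: int, qmin: float, qmax: float) -> np.ndarray:
    """Frequencies with density proportional to 1/q on [qmin, qmax]."""
    u = rng.random(size)
    return qmin * (qmax / qmin) ** u


def _allele_pairs(rng: np.random.Generator, size: int) -> tuple[np.ndarray, np.ndarray]:
    ref = rng.integers(0, 4, size)
    alt = (ref + rng.integers(1, 4, size)) % 4
    return _NUC[ref], _NUC[alt]


class _PanelBase:
    """Shared behavior of the two panel types."""

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_table)

    @property
    def arm_names(self) -> list[str]:
        return list(self.maps)

    def snp_indices_for_arm(self, arm: str) -> np.ndarray:
        return np.flatnonzero(self.snp_table["arm"].to_numpy() == arm)

    def snps_in_window(self, arm: str, start_bp: float, end_bp: float) -> np.ndarray:
        tab = self.snp_table
        mask = (tab["arm"].to_numpy() == arm) & (tab["bp"].to_numpy() >= start_bp) & (
            tab["bp"].to_numpy() <= end_bp
        )
        return np.flatnonzero(mask)


@dataclass
class GwasPanel(_PanelBase):
    line_ids: np.ndarray
    snp_table: pd.DataFrame  # arm, bp, cM, ref, alt, maf
    dosage: np.ndarray  # (n_lines, n_snps) int8 in {0, 2}, count of REF allele
    maps: dict[str, GeneticMap]

    def __post_init__(self):
        if self.dosage.shape != (len(self.line_ids), len(self.snp_table)):
            raise ValueError("dosage shape does not match line/snp counts")

    @property
    def maf(self) -> np.ndarray:
        return self.snp_table["maf"].to_numpy()

    def subset_lines(self, keep: np.ndarray) -> "GwasPanel":
        keep = np.asarray(keep)
        return GwasPanel(
            line_ids=self.line_ids[keep],
            snp_table=self.snp_table.copy(),
            dosage=self.dosage[keep],
            maps=self.maps,
        )

    def save(self, outdir) -> None:
        _save_common(self, outdir)
        np.save(Path(outdir) / "dosage.npy", self.dosage)

    @classmethod
    def load(cls, indir) -> "GwasPanel":
        indir = Path(indir)
        line_ids, snp_table, maps = _load_common(indir)
        return cls(line_ids, snp_table, np.load(indir / "dosage.npy"), maps)


@dataclass
class MppPanel(_PanelBase):
    line_ids: np.ndarray  # RIL ids
    founders: np.ndarray  # (8, n_snps) uint8, 1 = reference allele
    probs: np.ndarray  # (n_rils, n_grid, 8) float32, rows sum to 1
    grid: pd.DataFrame  # arm, bp, cM for each genotyped position
    snp_table: pd.DataFrame  # arm, bp, cM, ref, alt, maf, grid_index
    maps: dict[str, GeneticMap]

    def __post_init__(self):
        n, m, k = self.probs.shape
        if n != len(self.line_ids) or m != len(self.grid) or k != self.founders.shape[0]:
            raise ValueError("probability tensor shape mismatch")

    @property
    def n_founders(self) -> int:
        return self.founders.shape[0]

    @property
    def ril_ids(self) -> np.ndarray:
        return self.line_ids

    def check_probs(self, tol: float = 1e-8) -> None:
        s = self.probs.sum(axis=2)
        if not np.allclose(s, 1.0, atol=tol * max(1.0, float(np.abs(s).max()))):
            raise ValueError("founder probabilities do not sum to 1")
        if self.probs.min() < -tol or self.probs.max() > 1 + tol:
            raise ValueError("founder probabilities outside [0, 1]")

    def grid_indices_for_arm(self, arm: str) -> np.ndarray:
        return np.flatnonzero(self.grid["arm"].to_numpy() == arm)

    def nearest_grid_index(self, arm: str, bp: float) -> int:
        """Global index of the genotyped position closest to (arm, bp)."""
        idx = self.grid_indices_for_arm(arm)
        if idx.size == 0:
            raise KeyError(f"no genotyped positions on arm {arm!r}")
        pos = self.grid["bp"].to_numpy()[idx]
        return int(idx[np.argmin(np.abs(pos - bp))])

    def subset_lines(self, keep: np.ndarray) -> "MppPanel":
        keep = np.asarray(keep)
        return MppPanel(
            line_ids=self.line_ids[keep],
            founders=self.founders,
            probs=self.probs[keep],
            grid=self.grid.copy(),
            snp_table=self.snp_table.copy(),
            maps=self.maps,
        )

    def save(self, outdir) -> None:
        _save_common(self, outdir)
        outdir = Path(outdir)
        np.save(outdir / "probs.npy", self.probs)
        np.save(outdir / "founders.npy", self.founders)
        self.grid.to_csv(outdir / "grid.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, indir) -> "MppPanel":
        indir = Path(indir)
        line_ids, snp_table, maps = _load_common(indir)
        grid = pd.read_csv(indir / "grid.tsv", sep="\t")
        return cls(
            line_ids,
            np.load(indir / "founders.npy"),
            np.load(indir / "probs.npy"),
            grid,
            snp_table,
            maps,
        )


def _save_common(panel, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel.snp_table.to_csv(outdir / "snp_table.tsv", sep="\t", index=False)
    (outdir / "line_ids.txt").write_text("\n".join(map(str, panel.line_ids)) + "\n")
    meta = {
        arm: {"anchors_bp": m.anchors_bp.tolist(), "anchors_cm": m.anchors_cm.tolist()}
        for arm, m in panel.maps.items()
    }
    (outdir / "maps.json").write_text(json.dumps(meta, indent=1))


def _load_common(indir: Path):
    line_ids = np.array((indir / "line_ids.txt").read_text().split())
    snp_table = pd.read_csv(indir / "snp_table.tsv", sep="\t")
    meta = json.loads((indir / "maps.json").read_text())
    maps = {
        arm: GeneticMap(arm, np.array(d["anchors_bp"]), np.array(d["anchors_cm"]))
        for arm, d in meta.items()
    }
    return line_ids, snp_table, maps


# ---------------------------------------------------------------------------
# site catalogs (positions + underlying frequencies), shared across designs
# ---------------------------------------------------------------------------

def _site_positions(
    length_bp: int, count: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """``count`` distinct positions along an arm.

    Evenly spaced with uniform jitter of half the spacing, so local SNP
    counts are irregular as in real variant catalogs (exactly regular
    spacing would make e.g. three-SNP gene windows impossible at moderate
    density).
    """
    base = np.linspace(1, length_bp, count)
    if rng is not None and count > 1:
        half = (length_bp - 1) / (count - 1) / 2.0
        base = base + rng.uniform(-half, half, count)
    pos = np.unique(np.clip(np.round(base), 1, length_bp).astype(np.int64))
    return pos


def _default_catalog(cfg: PanelConfig, rng: np.random.Generator) -> pd.DataFrame:
    arms = list(cfg.arms)
    lengths = np.array([cfg.arms[a] for a in arms], dtype=float)
    counts = _allocate(cfg.n_snps, lengths)
    rows = []
    for arm, count in zip(arms, counts):
        pos = _site_positions(cfg.arms[arm], count, rng)
        q = _draw_spectrum(rng, pos.size, cfg.spectrum_qmin, cfg.spectrum_qmax)
        rows.append(pd.DataFrame({"arm": arm, "bp": pos, "q": q}))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# GWAS-style panel
# ---------------------------------------------------------------------------

def make_gwas_panel(cfg: PanelConfig, site_catalog: pd.DataFrame | None = None) -> GwasPanel:
    """Generate a panel of inbred lines with short-range LD and a skewed
    allele-frequency spectrum.

    Lines copy segments from a finite pool of ancestral haplotypes along
    each arm; the per-step switch probability ``1 - exp(-spacing/ld_scale)``
    makes pairwise r2 decay to the background level within a few multiples of
    ``cfg.ld_scale_bp``.  Line-specific Dirichlet weights over the pool
    create mild background relatedness.  SNPs with realized MAF below
    ``cfg.maf_floor`` are dropped.
    """
    seed = cfg.require_seed()
    maps = cfg.maps()
    if site_catalog is None:
        site_catalog = _default_catalog(cfg, rng_for(seed, "gwas", "catalog"))

    n, H = cfg.n_lines, cfg.haplotype_pool_size
    tables = []
    dosage_blocks = []
    for arm in cfg.arms:
        sites = site_catalog[site_catalog["arm"] == arm]
        if sites.empty:
            continue
        pos = sites["bp"].to_numpy(dtype=np.int64)
        q = sites["q"].to_numpy(dtype=float)
        S = pos.size
        rng = rng_for(seed, "gwas", "arm", arm)

        # Line-by-arm Dirichlet preferences over the ancestral pool create
        # background relatedness while keeping any one arm's genotypes
        # independent of the kinship built from the remaining arms (so the
        # LOCO correction does not soak up a focal SNP's own signal).
        weights = rng.dirichlet(np.full(H, cfg.pool_concentration), size=n)
        cdf = np.cumsum(weights, axis=1)
        cdf[:, -1] = 1.0

        pool = rng.random((H, S)) < (1.0 - q)[None, :]  # True = reference allele
        spacing = np.diff(pos, prepend=pos[0]).astype(float)
        p_switch = 1.0 - np.exp(-spacing / max(cfg.ld_scale_bp, 1e-9))
        switch = rng.random((n, S)) < p_switch[None, :]
        switch[:, 0] = True

        u = rng.random((n, S))
        draws = np.empty((n, S), dtype=np.int32)
        for i in range(n):
            draws[i] = np.searchsorted(cdf[i], u[i], side="right")
        np.clip(draws, 0, H - 1, out=draws)

        idx = np.where(switch, np.arange(S)[None, :], 0)
        np.maximum.accumulate(idx, axis=1, out=idx)
        hap = np.take_along_axis(draws, idx, axis=1)
        ref_allele = pool[hap, np.arange(S)[None, :]]
        dos = (2 * ref_allele).astype(np.int8)

        f_ref = ref_allele.mean(axis=0)
        maf = np.minimum(f_ref, 1.0 - f_ref)
        keep = maf >= cfg.maf_floor

        ref, alt = _allele_pairs(rng_for(seed, "gwas", "nuc", arm), S)
        tables.append(
            pd.DataFrame(
                {
                    "arm": arm,
                    "bp": pos[keep],
                    "cM": maps[arm].bp_to_cm(pos[keep]),
                    "ref": ref[keep],
                    "alt": alt[keep],
                    "maf": maf[keep],
                }
            )
        )
        dosage_blocks.append(dos[:, keep])

    snp_table = pd.concat(tables, ignore_index=True)
    dosage = np.hstack(dosage_blocks) if dosage_blocks else np.empty((n, 0), np.int8)
    line_ids = np.array([f"L{i:04d}" for i in range(n)])
    return GwasPanel(line_ids, snp_table, dosage, maps)


# ---------------------------------------------------------------------------
# MPP-style panel
# ---------------------------------------------------------------------------

def make_mpp_panel(cfg: PanelConfig, site_catalog: pd.DataFrame | None = None) -> MppPanel:
    """Generate an 8-founder multiparent RIL panel.

    Each RIL's genome is a founder mosaic: Poisson breakpoints on the genetic
    map at ``cfg.breakpoint_rate_per_cm`` per cM, with segment founders drawn
    from arm-level Dirichlet frequencies (founder drift).  The probability
    tensor encodes the true mosaic; a fraction ``cfg.ambiguity_fraction`` of
    (RIL, position) entries is blended with the uniform vector to emulate
    haplotype-inference uncertainty.  Founder SNPs outside the genotyped grid
    span are excluded, and SNPs with expected RIL MAF below ``cfg.maf_floor``
    are dropped.
    """
    seed = cfg.require_seed()
    if cfg.n_founders != 8:
        msg = f"multiparent emulation expects 8 founders, got {cfg.n_founders}"
        if cfg.strict_founders:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    maps = cfg.maps()
    K = cfg.n_founders
    n = cfg.n_lines
    if site_catalog is None:
        site_catalog = _default_catalog(cfg, rng_for(seed, "mpp", "catalog"))

    grid_frames = []
    prob_blocks = []
    founder_cols = []
    table_rows = []
    grid_offset = 0
    for arm in cfg.arms:
        gmap = maps[arm]
        length = cfg.arms[arm]
        gpos = np.arange(cfg.grid_spacing_bp, length + 1, cfg.grid_spacing_bp, dtype=np.int64)
        gcm = gmap.bp_to_cm(gpos)
        m = gpos.size
        arm_cm_len = float(gmap.bp_to_cm(length))

        rng = rng_for(seed, "mpp", "arm", arm)
        arm_weights = rng.dirichlet(np.full(K, cfg.founder_concentration))

        f_true = np.empty((n, m), dtype=np.int8)
        for r in range(n):
            nb = rng.poisson(cfg.breakpoint_rate_per_cm * arm_cm_len)
            segs = rng.choice(K, size=nb + 1, p=arm_weights)
            if nb == 0:
                f_true[r] = segs[0]
            else:
                breaks = np.sort(rng.uniform(0.0, arm_cm_len, nb))
                f_true[r] = segs[np.searchsorted(breaks, gcm, side="right")]

        P = np.zeros((n, m, K), dtype=np.float32)
        P[np.arange(n)[:, None], np.arange(m)[None, :], f_true] = 1.0
        if cfg.ambiguity_fraction > 0:
            mask = rng.random((n, m)) < cfg.ambiguity_fraction
            u = rng.uniform(0.3, 0.9, size=int(mask.sum())).astype(np.float32)
            P[mask] *= (1.0 - u)[:, None]
            P[mask] += (u / K)[:, None]

        sites = site_catalog[site_catalog["arm"] == arm]
        pos = sites["bp"].to_numpy(dtype=np.int64)
        q = sites["q"].to_numpy(dtype=float)
        in_span = (pos >= gpos[0]) & (pos <= gpos[-1])
        pos, q = pos[in_span], q[in_span]
        S = pos.size

        alt = rng.random((K, S)) < q[None, :]
        F = (~alt).astype(np.uint8)  # 1 = reference allele
        g_local = np.clip(
            np.round((pos - gpos[0]) / cfg.grid_spacing_bp).astype(np.int64), 0, m - 1
        )

        mean_p = P.mean(axis=0)  # (m, K) founder frequencies at each position
        f_ref = np.einsum("sk,sk->s", mean_p[g_local], F.T.astype(float))
        maf = np.minimum(f_ref, 1.0 - f_ref)
        keep = maf >= cfg.maf_floor

        ref, alt_nuc = _allele_pairs(rng_for(seed, "mpp", "nuc", arm), S)
        table_rows.append(
            pd.DataFrame(
                {
                    "arm": arm,
                    "bp": pos[keep],
                    "cM": gmap.bp_to_cm(pos[keep]),
                    "ref": ref[keep],
                    "alt": alt_nuc[keep],
                    "maf": maf[keep],
                    "grid_index": g_local[keep] + grid_offset,
                }
            )
        )
        founder_cols.append(F[:, keep])
        grid_frames.append(pd.DataFrame({"arm": arm, "bp": gpos, "cM": gcm}))
        prob_blocks.append(P)
        grid_offset += m

    grid = pd.concat(grid_frames, ignore_index=True)
    probs = np.concatenate(prob_blocks, axis=1)
    founders = np.hstack(founder_cols) if founder_cols else np.empty((K, 0), np.uint8)
    snp_table = pd.concat(table_rows, ignore_index=True)
    line_ids = np.array([f"RIL{i:04d}" for i in range(n)])
    return MppPanel(line_ids, founders, probs, grid, snp_table, maps)


# ---------------------------------------------------------------------------
# shared ancestral SNP pool for cross-panel validation experiments
# ---------------------------------------------------------------------------

def make_shared_panels(
    cfg_gwas: PanelConfig,
    cfg_mpp: PanelConfig,
    seed: int,
    frac_gwas_only: float = 0.59,
    frac_shared: float = 0.34,
    frac_mpp_only: float = 0.07,
    freq_logit_sd: float = 0.75,
) -> tuple[GwasPanel, MppPanel]:
    """Generate a GWAS panel and an MPP panel from one ancestral SNP pool.

    Each ancestral SNP is assigned to one of three classes (present only in
    the GWAS panel, shared, present only in the MPP panel); shared SNPs keep
    their physical coordinates in both panels, and per-panel frequencies are
    the ancestral frequency perturbed by logit-normal noise, so shared SNPs
    have correlated but unequal minor-allele frequencies across panels.
    """
    fracs = np.array([frac_gwas_only, frac_shared, frac_mpp_only], dtype=float)
    if np.any(fracs < 0) or fracs.sum() <= 0:
        raise ValueError("class fractions must be non-negative with positive sum")
    fracs = fracs / fracs.sum()
    if cfg_gwas.arms != cfg_mpp.arms:
        raise ValueError("shared panels require identical arm definitions")

    n_anc = int(round(cfg_gwas.n_snps / (fracs[0] + fracs[1])))
    base_cfg = PanelConfig(
        n_lines=2,
        n_snps=n_anc,
        arms=dict(cfg_gwas.arms),
        cm_per_mb=cfg_gwas.cm_per_mb,
        spectrum_qmin=cfg_gwas.spectrum_qmin,
        spectrum_qmax=cfg_gwas.spectrum_qmax,
        seed=0,
    )
    rng = rng_for(seed, "shared", "catalog")
    catalog = _default_catalog(base_cfg, rng)
    cls = rng.choice(3, size=len(catalog), p=fracs)

    def _perturb(q: np.ndarray, stream: str) -> np.ndarray:
        r = rng_for(seed, "shared", stream)
        logit = np.log(q / (1 - q)) + r.normal(0.0, freq_logit_sd, q.size)
        return 1.0 / (1.0 + np.exp(-logit))

    gwas_sites = catalog[cls <= 1].copy()
    gwas_sites["q"] = _perturb(gwas_sites["q"].to_numpy(), "gwas-freq")
    mpp_sites = catalog[cls >= 1].copy()
    mpp_sites["q"] = _perturb(mpp_sites["q"].to_numpy(), "mpp-freq")

    cfg_g = _with_seed(cfg_gwas, seed, "shared-gwas")
    cfg_m = _with_seed(cfg_mpp, seed, "shared-mpp")
    return make_gwas_panel(cfg_g, site_catalog=gwas_sites), make_mpp_panel(
        cfg_m, site_catalog=mpp_sites
    )


def _with_seed(cfg: PanelConfig, root: int, tag: str) -> PanelConfig:
    d = asdict(cfg)
    d["seed"] = int(rng_for(root, tag).integers(0, 2**31 - 1))
    return PanelConfig(**d)


def make_gene_catalog(
    arms: dict[str, int],
    n_genes: int,
    seed: int,
    gene_length: int = 2_000,
) -> pd.DataFrame:
    """Random fixed-length gene windows (start/end bp, no flanks included)."""
    rng = rng_for(seed, "genes")
    names = list(arms)
    lengths = np.array([arms[a] for a in names], dtype=float)
    pick = rng.choice(len(names), size=n_genes, p=lengths / lengths.sum())
    starts = np.empty(n_genes, dtype=np.int64)
    for i, a in enumerate(pick):
        starts[i] = rng.integers(1, arms[names[a]] - gene_length)
    return pd.DataFrame(
        {
            "gene_id": [f"G{i:05d}" for i in range(n_genes)],
            "arm": [names[a] for a in pick],
            "start": starts,
            "end": starts + gene_length,
        }
    )


# ---------------------------------------------------------------------------
# optional VCF adapter (inbred lines coded as homozygous diploids)
# ---------------------------------------------------------------------------

def export_vcf(panel: GwasPanel, path) -> None:
    """Write a GWAS panel as VCF; dosage 2 (REF) -> 0/0, dosage 0 -> 1/1."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for arm, m in panel.maps.items():
        header.contigs.add(arm, length=m.length_bp)
    for lid in panel.line_ids:
        header.add_sample(str(lid))
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        tab = panel.snp_table
        arms = tab["arm"].to_numpy()
        bps = tab["bp"].to_numpy()
        refs = tab["ref"].to_numpy()
        alts = tab["alt"].to_numpy()
        for j in range(len(tab)):
            rec = vf.new_record(
                contig=str(arms[j]), start=int(bps[j]) - 1, alleles=(str(refs[j]), str(alts[j]))
            )
            for i, lid in enumerate(panel.line_ids):
                g = 0 if panel.dosage[i, j] == 2 else 1
                rec.samples[str(lid)]["GT"] = (g, g)
            vf.write(rec)


def import_vcf(path, cm_per_mb: float = 2.5, on_het: str = "error") -> GwasPanel:
    """Read a homozygous-diploid VCF back into a :class:`GwasPanel`.

    ``on_het`` controls records with heterozygous calls, which are
    inconsistent with fully inbred lines: ``"error"`` raises, ``"drop"``
    silently removes the record.
    """
    import pysam

    if on_het not in ("error", "drop"):
        raise ValueError("on_het must be 'error' or 'drop'")
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        contigs = {c: vf.header.contigs[c].length for c in vf.header.contigs}
        rows, cols = [], []
        for rec in vf:
            gts = [rec.samples[s]["GT"] for s in samples]
            if any(g[0] != g[1] for g in gts):
                if on_het == "error":
                    raise ValueError(
                        f"heterozygous call at {rec.contig}:{rec.pos}; inbred lines expected"
                    )
                continue
            dos = np.array([2 if g[0] == 0 else 0 for g in gts], dtype=np.int8)
            f_ref = dos.mean() / 2.0
            rows.append(
                (
                    rec.contig,
                    rec.pos,
                    rec.pos * cm_per_mb / 1e6,
                    rec.ref,
                    rec.alts[0] if rec.alts else "N",
                    min(f_ref, 1 - f_ref),
                )
            )
            cols.append(dos)
    snp_table = pd.DataFrame(rows, columns=["arm", "bp", "cM", "ref", "alt", "maf"])
    dosage = np.stack(cols, axis=1) if cols else np.empty((len(samples), 0), np.int8)
    maps = {
        arm: GeneticMap.linear(arm, contigs[arm] or int(snp_table["bp"].max()), cm_per_mb)
        for arm in snp_table["arm"].unique()
    }
    return GwasPanel(np.array(samples), snp_table, dosage, maps)
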