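"""Power, effect-size bias, and validation experiments.

Each experiment cell plants one causative locus per replicate at a random
eligible site, scans the surrounding +/- 5 Mb region with the mixed model,
and calls the locus mapped when the peak LOD strictly exceeds the
genome-wide FWER threshold.  The winner's-curse summary of a cell is the
inflation factor: the mean estimated PVE among the mapped replicates divided
by the true simulated PVE.  When power is low, replicates are escalated in
batches until a minimum number of detections has accumulated (or a cap is
reached), so the conditional mean is estimated from a reasonable sample.

Validation re-simulates a mapped locus — with fresh noise in the same panel,
or with its effect carried into a second panel sharing part of the SNP pool —
and judges success at the less stringent local-region threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import child_sequence, rng_for
from .panels import (
    GwasPanel,
    MppPanel,
    PanelConfig,
    make_gwas_panel,
    make_mpp_panel,
    make_gene_catalog,
)
from .phenotypes import (
    GeneIntervalError,
    MonomorphicError,
    QtlSpec,
    simulate_biallelic,
    simulate_multiallelic,
    transfer_effect,
)
from .mapping import MappingContext, call_mapped

__all__ = [
    "ExperimentConfig",
    "CellResult",
    "ValidationSummary",
    "BetweenPanelSummary",
    "build_context",
    "run_power_bias",
    "unconditional_pve",
    "run_validation_within",
    "run_validation_between",
    "DesignStudy",
    "run_design_study",
    "summary_table",
    "DESIGN_DEFAULTS",
]

#: Desk-scale generator defaults per design: a 110 Mb, five-arm genome with
#: 2 SNPs/kb for the GWAS panel and 1 founder SNP/kb (plus the 10 kb
#: genotyping grid) for the multiparent panel.
DESIGN_DEFAULTS = {
    "gwas": {"n_snps": 220_000},
    "mpp": {"n_snps": 110_000},
}


@dataclass
class ExperimentConfig:
    """Declarative description of a study grid (used by the CLI)."""

    design: str = "mpp"
    sample_sizes: tuple[int, ...] = (100, 185, 500, 878)
    z_grid: tuple[float, ...] = (0.05, 0.10, 0.20)
    kind: str = "biallelic"
    base_replicates: int = 1000
    min_detections: int = 30
    escalation_cap: int = 6  # max replicates = cap * base_replicates
    n_null_scans: int = 2000
    alpha: float = 0.05
    n_snps: int | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.design not in ("gwas", "mpp"):
            raise ValueError("design must be 'gwas' or 'mpp'")
        if self.kind not in ("biallelic", "multiallelic"):
            raise ValueError("kind must be 'biallelic' or 'multiallelic'")
        if self.min_detections < 1 or self.base_replicates < 1:
            raise ValueError("replicate counts must be positive")


def build_context(
    design: str,
    n_lines: int,
    seed: int,
    n_snps: int | None = None,
    arms: dict[str, int] | None = None,
    dtype=np.float64,
    **cfg_overrides,
) -> MappingContext:
    """Generate a panel for one (design, sample size) and prepare its
    mapping context (LOCO kinships, eigendecompositions, rotated designs)."""
    if n_snps is None:
        n_snps = DESIGN_DEFAULTS[design]["n_snps"]
    cfg = PanelConfig(n_lines=n_lines, n_snps=n_snps, arms=arms, seed=seed, **cfg_overrides)
    panel = make_gwas_panel(cfg) if design == "gwas" else make_mpp_panel(cfg)
    return MappingContext(panel, dtype=dtype)


@dataclass
class CellResult:
    """One experiment cell: (design, n, z, QTL kind)."""

    design: str
    n_lines: int
    z: float
    kind: str
    n_simulated: int
    n_mapped: int
    low_confidence: bool
    records: pd.DataFrame

    @property
    def power_pct(self) -> float:
        return 100.0 * self.n_mapped / self.n_simulated if self.n_simulated else np.nan

    @property
    def mean_peak_pve_mapped(self) -> float:
        sel = self.records.loc[self.records["mapped"], "peak_pve"]
        return float(sel.mean()) if len(sel) else np.nan

    @property
    def inflation(self) -> float:
        return self.mean_peak_pve_mapped / self.z

    @property
    def mean_true_pve(self) -> float:
        return float(self.records["true_pve"].mean()) if len(self.records) else np.nan


def _simulate_at(panel, kind: str, snp_indices: tuple[int, ...], z: float, rng):
    """Fresh phenotypes at a fixed locus (same component SNPs)."""
    if kind == "biallelic":
        return simulate_biallelic(panel, snp_indices[0], z, rng)
    from .phenotypes import _finish, _realized_dosage  # same-package helpers

    alt = np.zeros(panel.n_lines)
    for s in snp_indices:
        alt += 1.0 - _realized_dosage(panel, int(s), rng) / 2.0
    row = panel.snp_table.iloc[int(snp_indices[0])]
    return _finish(
        panel,
        alt,
        dict(
            kind="multiallelic",
            snp_indices=tuple(int(s) for s in snp_indices),
            arm=str(row["arm"]),
            bp=int(row["bp"]),
            source_panel=type(panel).__name__,
        ),
        rng,
        z,
    )


def _draw_phenotype(panel, kind: str, z: float, rng, gene_catalog, max_tries: int = 500):
    for _ in range(max_tries):
        try:
            if kind == "biallelic":
                snp = int(rng.integers(0, panel.n_snps))
                return simulate_biallelic(panel, snp, z, rng)
            gi = int(rng.integers(0, len(gene_catalog)))
            g = gene_catalog.iloc[gi]
            return simulate_multiallelic(
                panel, (str(g["arm"]), int(g["start"]), int(g["end"])), z, rng
            )
        except (MonomorphicError, GeneIntervalError):
            continue
    raise RuntimeError("could not draw an eligible QTL site")


def run_power_bias(
    ctx: MappingContext,
    threshold: float,
    z: float,
    seed,
    kind: str = "biallelic",
    base_replicates: int = 1000,
    min_detections: int = 30,
    max_replicates: int | None = None,
    gene_catalog: pd.DataFrame | None = None,
    halfwidth_bp: float = 5e6,
) -> CellResult:
    """Simulate, map and summarize one experiment cell.

    Replicates run in batches of ``base_replicates`` until at least
    ``min_detections`` loci are mapped or ``max_replicates`` (default six
    batches) is reached; a cell that still has too few detections is flagged
    low-confidence.
    """
    panel = ctx.panel
    if max_replicates is None:
        max_replicates = 6 * base_replicates
    if kind == "multiallelic" and gene_catalog is None:
        arms = {a: m.length_bp for a, m in panel.maps.items()}
        gene_catalog = make_gene_catalog(arms, 2000, rng_for(seed, "genes").integers(2**31))

    rows = []
    n_mapped = 0
    rep = 0
    total = min(base_replicates, max_replicates)
    while True:
        while rep < total:
            rng = rng_for(seed, "rep", rep)
            ph = _draw_phenotype(panel, kind, z, rng, gene_catalog)
            spec = ph.spec
            arm, center = ctx.center_for_snp(spec.snp_indices[0])
            scan = ctx.scan_region(ph.y, arm, center, halfwidth_bp)
            mapped, peak_pve = call_mapped(scan, threshold)
            n_mapped += mapped
            rows.append(
                {
                    "rep": rep,
                    "kind": kind,
                    "z": z,
                    "snp_indices": ";".join(map(str, spec.snp_indices)),
                    "arm": arm,
                    "bp": spec.bp,
                    "center_bp": center,
                    "sigma2_g": spec.sigma2_g,
                    "peak_lod": scan.peak_lod,
                    "peak_bp": scan.peak_position,
                    "peak_pve": peak_pve,
                    "mapped": bool(mapped),
                    "true_pve": ctx.pve_at(scan, center),
                }
            )
            rep += 1
        if n_mapped >= min_detections or total >= max_replicates:
            break
        total = min(total + base_replicates, max_replicates)

    return CellResult(
        design=ctx.design,
        n_lines=ctx.n,
        z=z,
        kind=kind,
        n_simulated=rep,
        n_mapped=n_mapped,
        low_confidence=n_mapped < min_detections,
        records=pd.DataFrame(rows),
    )


def unconditional_pve(cell: CellResult) -> dict:
    """Distribution of the PVE estimated at the true causative position for
    *all* replicates, regardless of significance."""
    v = cell.records["true_pve"].to_numpy()
    qs = np.quantile(v, [0.025, 0.25, 0.5, 0.75, 0.975]) if v.size else [np.nan] * 5
    return {
        "design": cell.design,
        "n_lines": cell.n_lines,
        "z": cell.z,
        "n": int(v.size),
        "mean": float(v.mean()) if v.size else np.nan,
        "q2.5": float(qs[0]),
        "q25": float(qs[1]),
        "median": float(qs[2]),
        "q75": float(qs[3]),
        "q97.5": float(qs[4]),
    }


@dataclass
class ValidationSummary:
    n_candidates: int
    n_attempted: int
    n_validated: int

    @property
    def validated_pct(self) -> float:
        return 100.0 * self.n_validated / self.n_attempted if self.n_attempted else np.nan


def run_validation_within(
    ctx: MappingContext,
    cell: CellResult,
    local_threshold: float,
    seed,
    max_revalidate: int = 100,
    halfwidth_bp: float = 5e6,
) -> ValidationSummary:
    """Re-simulate mapped loci in the same panel and re-map locally.

    A fresh phenotype is generated at each mapped locus with the same true
    PVE and sample size; validation succeeds when the local +/- 5 Mb scan
    exceeds the local-region FWER threshold.  When more than
    ``max_revalidate`` loci were mapped, a random subset of that size is
    re-tested (the subsampling stream is part of the seed hierarchy).
    """
    mapped = cell.records[cell.records["mapped"]]
    if mapped.empty:
        return ValidationSummary(0, 0, 0)
    if len(mapped) > max_revalidate:
        pick = rng_for(seed, "subsample").choice(len(mapped), max_revalidate, replace=False)
        mapped = mapped.iloc[np.sort(pick)]
    n_val = 0
    for k, (_, rec) in enumerate(mapped.iterrows()):
        rng = rng_for(seed, "validate", k)
        snps = tuple(int(s) for s in str(rec["snp_indices"]).split(";"))
        ph = _simulate_at(ctx.panel, cell.kind, snps, cell.z, rng)
        scan = ctx.scan_region(ph.y, str(rec["arm"]), float(rec["center_bp"]), halfwidth_bp)
        n_val += scan.peak_lod > local_threshold
    return ValidationSummary(int(cell.n_mapped), len(mapped), int(n_val))


@dataclass
class BetweenPanelSummary:
    n_hits: int
    n_shared: int
    n_validated: int

    @property
    def shared_pct(self) -> float:
        return 100.0 * self.n_shared / self.n_hits if self.n_hits else np.nan

    @property
    def validated_pct(self) -> float:
        return 100.0 * self.n_validated / self.n_shared if self.n_shared else np.nan


def run_validation_between(
    source_cell: CellResult,
    target_ctx: MappingContext,
    local_threshold: float,
    seed,
    maf_floor: float = 0.025,
    halfwidth_bp: float = 5e6,
) -> BetweenPanelSummary:
    """Carry mapped biallelic hits from a source panel into a target panel.

    The locus effect is fixed by the source panel (its noise variance), so
    the realized PVE in the target follows the target allele frequency.  A
    hit whose SNP does not segregate in the target cannot validate; shared
    hits are scanned locally and judged at the target's local threshold.
    """
    if source_cell.kind != "biallelic":
        raise ValueError("between-panel validation considers the biallelic case only")
    mapped = source_cell.records[source_cell.records["mapped"]]
    n_shared = 0
    n_val = 0
    for k, (_, rec) in enumerate(mapped.iterrows()):
        rng = rng_for(seed, "between", k)
        spec = QtlSpec(
            kind="biallelic",
            snp_indices=(int(str(rec["snp_indices"]).split(";")[0]),),
            arm=str(rec["arm"]),
            bp=int(rec["bp"]),
            z=float(rec["z"]),
            sigma2_g=float(rec["sigma2_g"]),
            genetic_values=np.zeros(2),
            source_panel=source_cell.design,
        )
        res = transfer_effect(spec, target_ctx.panel, rng, maf_floor=maf_floor)
        if not res.shared:
            continue
        n_shared += 1
        arm, bp = spec.arm, spec.bp
        if target_ctx.design == "mpp":
            g = target_ctx.panel.nearest_grid_index(arm, bp)
            bp = int(target_ctx.panel.grid["bp"].iloc[g])
        scan = target_ctx.scan_region(res.phenotypes.y, arm, bp, halfwidth_bp)
        n_val += scan.peak_lod > local_threshold
    return BetweenPanelSummary(len(mapped), n_shared, int(n_val))


@dataclass
class DesignStudy:
    """Thresholds plus power/bias cells for one (design, sample size)."""

    design: str
    n_lines: int
    n_snps: int
    thresholds: "ThresholdSet"
    nulls: "NullScanSet"
    cells: dict[float, CellResult]

    def local_power_pct(self, z: float) -> float:
        """Power of the same replicates judged at the local-region threshold
        (the validation-scan criterion)."""
        rec = self.cells[z].records
        return 100.0 * float((rec["peak_lod"] > self.thresholds.local).mean())


def run_design_study(
    design: str,
    n_lines: int,
    z_values: tuple[float, ...],
    seed,
    n_null_scans: int = 200,
    base_replicates: int = 200,
    min_detections: int = 30,
    max_replicates: int | None = None,
    n_snps: int | None = None,
    arms: dict[str, int] | None = None,
    alpha: float = 0.05,
    dtype=np.float32,
    kind: str = "biallelic",
) -> DesignStudy:
    """End-to-end study for one panel: generate, derive FWER thresholds from
    null scans, and run one power/bias cell per true PVE.

    The mapping context is released before returning, so several studies can
    be composed without holding every panel's rotated design in memory.
    """
    from .thresholds import ThresholdSet, null_scans

    ctx = build_context(
        design, n_lines, int(rng_for(seed, "panel").integers(2**31 - 1)),
        n_snps=n_snps, arms=arms, dtype=dtype,
    )
    nulls = null_scans(ctx, n_null_scans, child_sequence(seed, "nulls"))
    thr = ThresholdSet.from_null_scans(nulls, alpha)
    cells = {}
    for z in z_values:
        cells[z] = run_power_bias(
            ctx,
            thr.genome_wide,
            z,
            seed=child_sequence(seed, "cell", int(round(z * 1000))),
            kind=kind,
            base_replicates=base_replicates,
            min_detections=min_detections,
            max_replicates=max_replicates,
        )
    return DesignStudy(
        design=design,
        n_lines=n_lines,
        n_snps=ctx.panel.n_snps,
        thresholds=thr,
        nulls=nulls,
        cells=cells,
    )


def summary_table(cells: list[CellResult], validations: list | None = None) -> pd.DataFrame:
    """Tabular study summary, one row per cell (power, bias, validation)."""
    rows = []
    for i, c in enumerate(cells):
        row = {
            "design": c.design,
            "kind": c.kind,
            "true_pve": c.z,
            "n_lines": c.n_lines,
            "n_simulated": c.n_simulated,
            "n_mapped": c.n_mapped,
            "power_pct": c.power_pct,
            "mean_peak_pve_mapped": c.mean_peak_pve_mapped,
            "inflation": c.inflation,
            "mean_true_pve": c.mean_true_pve,
            "low_confidence": c.low_confidence,
        }
        if validations is not None and validations[i] is not None:
            row["validated_pct"] = validations[i].validated_pct
        rows.append(row)
    return pd.DataFrame(rows)
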