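"""Simulated QTL phenotypes.

A single causative locus is planted per phenotype.  For a target fraction of
phenotypic variance explained ``z``, environmental noise with variance
``(1 - z)/z * sigma2_G`` is added to the genetic values, where ``sigma2_G``
is the empirical variance of the genetic values in the simulated sample, so
the expected realized PVE equals ``z``.

Biallelic QTL use the line's SNP dosage as the genetic value.  Multiallelic
QTL sum the alternative-allele counts of three SNPs inside one gene window
(000 -> 0, 001 -> 1, 011 -> 2, ..., 111 -> 3).  Cross-panel transfer keeps
the *source* panel's noise variance fixed, so the realized PVE in the target
panel rises or falls with the allele frequency there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panels import GwasPanel, MppPanel
from .kinship import impute_ref_prob, sample_genotypes
from ._rng import rng_for

__all__ = [
    "QtlSpec",
    "PhenotypeSet",
    "TransferResult",
    "MonomorphicError",
    "GeneIntervalError",
    "simulate_biallelic",
    "simulate_multiallelic",
    "transfer_effect",
]


class MonomorphicError(ValueError):
    """Realized genotypes at the chosen locus carry no variation."""


class GeneIntervalError(ValueError):
    """A gene window does not contain enough eligible SNPs."""


@dataclass
class QtlSpec:
    kind: str  # "biallelic" | "multiallelic"
    snp_indices: tuple[int, ...]
    arm: str
    bp: int  # position of the (first) component SNP
    z: float
    sigma2_g: float
    genetic_values: np.ndarray
    source_panel: str = "unknown"

    def __post_init__(self):
        if not (0.0 < self.z < 1.0):
            raise ValueError("true PVE z must lie in (0, 1)")
        if self.sigma2_g <= 0:
            raise MonomorphicError("genetic variance must be positive")


@dataclass
class PhenotypeSet:
    line_ids: np.ndarray
    y: np.ndarray
    spec: QtlSpec
    noise_seed: int | None = None

    def __post_init__(self):
        if len(self.y) != len(self.line_ids):
            raise ValueError("phenotype length must match line count")


def _noise_variance(z: float, sigma2_g: float) -> float:
    return (1.0 - z) / z * sigma2_g


def _finish(panel, values: np.ndarray, spec_kwargs: dict, rng, z: float) -> PhenotypeSet:
    sigma2_g = float(np.var(values))
    if sigma2_g <= 0:
        raise MonomorphicError("monomorphic genetic values")
    spec = QtlSpec(z=z, sigma2_g=sigma2_g, genetic_values=values, **spec_kwargs)
    e = rng.normal(0.0, np.sqrt(_noise_variance(z, sigma2_g)), size=values.size)
    return PhenotypeSet(panel.line_ids, values + e, spec)


def _realized_dosage(panel, snp_index: int, rng) -> np.ndarray:
    """Dosage vector in {0, 2} at a SNP; for the MPP, genotypes are first
    realized by a binomial draw from the imputed Prob(REF)."""
    if isinstance(panel, MppPanel):
        return sample_genotypes(impute_ref_prob(panel, snp_index), rng)
    return panel.dosage[:, int(snp_index)].astype(np.int8)


def simulate_biallelic(
    panel,
    snp_index: int,
    z: float,
    seed,
    on_monomorphic: str = "resample",
    max_resample: int = 20,
) -> PhenotypeSet:
    """Phenotypes for a single biallelic QTL at ``snp_index`` with true PVE ``z``.

    For the MPP the realized dosages are binomial draws from Prob(REF); if
    they come out monomorphic the draw is repeated (``on_monomorphic =
    'resample'``) or the locus is rejected (``'reject'``).
    """
    rng = seed if isinstance(seed, np.random.Generator) else rng_for(seed, "biallelic")
    row = panel.snp_table.iloc[int(snp_index)]
    tries = max_resample if on_monomorphic == "resample" else 1
    for _ in range(tries):
        dos = _realized_dosage(panel, snp_index, rng)
        if np.ptp(dos) > 0:
            return _finish(
                panel,
                dos.astype(np.float64),
                dict(
                    kind="biallelic",
                    snp_indices=(int(snp_index),),
                    arm=str(row["arm"]),
                    bp=int(row["bp"]),
                    source_panel=type(panel).__name__,
                ),
                rng,
                z,
            )
    raise MonomorphicError(f"SNP {snp_index} realized monomorphic genotypes")


def simulate_multiallelic(
    panel,
    gene_interval: tuple[str, int, int],
    z: float,
    seed,
    flank_bp: int = 1_000,
    n_component_snps: int = 3,
) -> PhenotypeSet:
    """Phenotypes for a gene-based multiallelic QTL.

    Three SNPs are drawn at random from the gene window extended by
    ``flank_bp`` on each side; each line's genetic value is its total count
    of alternative alleles across the three SNPs (0-3).  Raises
    :class:`GeneIntervalError` when fewer than three eligible SNPs fall in
    the window, and :class:`MonomorphicError` when the realized sum carries
    no variation (callers draw a new gene in either case).
    """
    rng = seed if isinstance(seed, np.random.Generator) else rng_for(seed, "multiallelic")
    arm, start, end = gene_interval
    cand = panel.snps_in_window(arm, start - flank_bp, end + flank_bp)
    if cand.size < n_component_snps:
        raise GeneIntervalError(
            f"window {arm}:{start}-{end} (+/-{flank_bp}) holds {cand.size} SNPs; "
            f"{n_component_snps} required"
        )
    chosen = np.sort(rng.choice(cand, size=n_component_snps, replace=False))
    # count of alternative alleles per line: dosage counts REF copies on {0,2}
    alt_counts = np.zeros(panel.n_lines, dtype=np.float64)
    for s in chosen:
        alt_counts += 1.0 - _realized_dosage(panel, int(s), rng) / 2.0
    row = panel.snp_table.iloc[int(chosen[0])]
    return _finish(
        panel,
        alt_counts,
        dict(
            kind="multiallelic",
            snp_indices=tuple(int(s) for s in chosen),
            arm=str(row["arm"]),
            bp=int(row["bp"]),
            source_panel=type(panel).__name__,
        ),
        rng,
        z,
    )


@dataclass
class TransferResult:
    """Outcome of re-simulating a mapped QTL in a second panel."""

    shared: bool
    reason: str = ""
    phenotypes: PhenotypeSet | None = None
    expected_pve: float | None = None


def transfer_effect(
    source_spec: QtlSpec,
    target_panel,
    seed,
    maf_floor: float = 0.025,
) -> TransferResult:
    """Simulate a source-panel QTL in a target panel with its effect fixed.

    The environmental variance is held at the source value
    ``(1 - z)/z * sigma2_G(source)``; the genetic values come from the target
    panel's genotypes at the same (arm, bp).  The expected realized PVE in
    the target is ``s2_t / (s2_t + Ve)``, larger when the target
    minor-allele frequency is larger.  When the SNP is absent from the
    target's filtered table (not shared, or below the MAF floor there) no
    phenotype is produced.
    """
    rng = seed if isinstance(seed, np.random.Generator) else rng_for(seed, "transfer")
    tab = target_panel.snp_table
    hit = np.flatnonzero(
        (tab["arm"].to_numpy() == source_spec.arm) & (tab["bp"].to_numpy() == source_spec.bp)
    )
    if hit.size == 0:
        return TransferResult(False, "SNP not segregating in target panel")
    j = int(hit[0])
    if float(tab["maf"].iloc[j]) < maf_floor:
        return TransferResult(False, "SNP below MAF floor in target panel")

    dos = _realized_dosage(target_panel, j, rng).astype(np.float64)
    s2_t = float(np.var(dos))
    if s2_t <= 0:
        return TransferResult(False, "SNP realized monomorphic in target panel")
    ve = _noise_variance(source_spec.z, source_spec.sigma2_g)
    spec = QtlSpec(
        kind="biallelic",
        snp_indices=(j,),
        arm=source_spec.arm,
        bp=source_spec.bp,
        z=s2_t / (s2_t + ve),
        sigma2_g=s2_t,
        genetic_values=dos,
        source_panel=f"transfer:{source_spec.source_panel}",
    )
    y = dos + rng.normal(0.0, np.sqrt(ve), size=dos.size)
    return TransferResult(
        True,
        "",
        PhenotypeSet(target_panel.line_ids, y, spec),
        expected_pve=s2_t / (s2_t + ve),
    )
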