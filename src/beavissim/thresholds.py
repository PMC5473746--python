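"""Null-scan significance thresholds and false-positive-rate curves.

Family-wise error is controlled empirically: phenotypes with no causative
locus are generated (i.i.d. standard normal across lines), the full genome
is scanned, and the genome-wide maximum LOD of each null scan is recorded.
The FWER-5% threshold is the empirical 95th percentile of those maxima.  A
local-region variant takes the maximum within a +/- 5 Mb window at a random
position instead, giving the less stringent threshold appropriate for a
focused validation scan.

Clustered null signals are collapsed into independent peaks before counting
false positives: a peak within a fixed genetic distance of a higher peak is
eliminated (2 cM for the MPP design with its long-range LD, 0.5 cM for the
GWAS design).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from ._rng import rng_for
from .mapping import MappingContext, GenomeScan

__all__ = [
    "NullScanSet",
    "ThresholdSet",
    "null_scans",
    "fwer_threshold",
    "local_fwer_threshold",
    "prune_peaks",
    "fpr_curve",
    "p_to_lod",
    "PRUNE_RADIUS_CM",
]

#: Peak-pruning radii (cM) by design, reflecting each panel's LD structure.
PRUNE_RADIUS_CM = {"gwas": 0.5, "mpp": 2.0}


@dataclass
class NullScanSet:
    """Summaries of genome scans for phenotypes with no simulated QTL."""

    design: str
    n_lines: int
    n_scans: int
    max_lods: np.ndarray  # genome-wide maximum per scan
    local_max_lods: np.ndarray  # max within a random +/- 5 Mb window per scan
    peak_lods: list[np.ndarray]  # pruned independent peak LODs per scan
    prune_radius_cm: float


def null_scans(
    ctx: MappingContext,
    n_scans: int,
    seed,
    local_halfwidth_bp: float = 5e6,
    prune_radius_cm: float | None = None,
) -> NullScanSet:
    """Scan ``n_scans`` random phenotypes with no simulated QTL.

    For each scan the genome-wide maximum LOD, the maximum within a random
    +/- 5 Mb window, and the pruned independent peak list are recorded.
    Deterministic given the seed.
    """
    if n_scans < 2:
        raise ValueError("need at least 2 null scans")
    if prune_radius_cm is None:
        prune_radius_cm = PRUNE_RADIUS_CM[ctx.design]
    n = ctx.n
    max_lods = np.empty(n_scans)
    local_max = np.empty(n_scans)
    peaks: list[np.ndarray] = []
    for s in range(n_scans):
        rng = rng_for(seed, "null-scan", s)
        y = rng.standard_normal(n)
        scan = ctx.scan_genome(y)
        max_lods[s] = scan.max_lod
        j = int(rng.integers(0, scan.lod.size))
        local_max[s] = scan.window_max(
            int(scan.arm_codes[j]), float(scan.positions_bp[j]), local_halfwidth_bp
        )
        keep = prune_peaks(scan.positions_cm, scan.lod, prune_radius_cm,
                           arm_codes=scan.arm_codes)
        peaks.append(scan.lod[keep])
    return NullScanSet(
        design=ctx.design,
        n_lines=n,
        n_scans=n_scans,
        max_lods=max_lods,
        local_max_lods=local_max,
        peak_lods=peaks,
        prune_radius_cm=prune_radius_cm,
    )


def fwer_threshold(null_dist, alpha: float = 0.05) -> float:
    """Empirical (1 - alpha) quantile of the null maximum-LOD sample.

    Uses type-7 linear interpolation; with ``alpha = 0`` this is the sample
    maximum and with ``alpha = 1`` the minimum.
    """
    lods = null_dist.max_lods if isinstance(null_dist, NullScanSet) else np.asarray(null_dist)
    if lods.size < 20:
        raise ValueError("need at least 20 null scans for a threshold")
    return float(np.quantile(lods, 1.0 - alpha, method="linear"))


def local_fwer_threshold(null_dist, alpha: float = 0.05) -> float:
    """FWER threshold for a +/- 5 Mb validation scan, from the random-window
    maxima of the null scans.  Never exceeds the genome-wide threshold on
    the same scans."""
    if not isinstance(null_dist, NullScanSet):
        raise TypeError("local_fwer_threshold needs a NullScanSet")
    if null_dist.local_max_lods.size < 20:
        raise ValueError("need at least 20 null scans for a threshold")
    return float(np.quantile(null_dist.local_max_lods, 1.0 - alpha, method="linear"))


def _local_maxima(lod: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; plateaus collapse to their leftmost
    point; an endpoint counts when it exceeds its single neighbor."""
    lod = np.asarray(lod, dtype=float)
    n = lod.size
    if n == 0:
        return np.empty(0, dtype=np.intp)
    change = np.empty(n, dtype=bool)
    change[0] = True
    np.not_equal(lod[1:], lod[:-1], out=change[1:])
    starts = np.flatnonzero(change)  # leftmost index of each equal-value run
    vals = lod[starts]
    left = np.concatenate(([-np.inf], vals[:-1]))
    right = np.concatenate((vals[1:], [-np.inf]))
    return starts[(vals > left) & (vals > right)]


def prune_peaks(
    positions_cm: np.ndarray,
    lods: np.ndarray,
    radius_cm: float,
    arm_codes: np.ndarray | None = None,
) -> np.ndarray:
    """Collapse clustered peaks into independent signals.

    Local maxima are ranked by LOD (descending; ties favor the smaller
    coordinate) and any peak within ``radius_cm`` of an already-retained
    higher peak on the same arm is eliminated.  Returns indices into the
    input arrays, sorted by position.
    """
    from bisect import bisect_left, insort

    positions_cm = np.asarray(positions_cm, dtype=float)
    lods = np.asarray(lods, dtype=float)
    if arm_codes is None:
        arm_codes = np.zeros(lods.size, dtype=np.int16)
    kept: list[int] = []
    for code in np.unique(arm_codes):
        idx = np.flatnonzero(arm_codes == code)
        cand = idx[_local_maxima(lods[idx])]
        order = sorted(cand, key=lambda i: (-lods[i], positions_cm[i], i))
        retained_cm: list[float] = []  # sorted; only neighbors can conflict
        for i in order:
            cm = positions_cm[i]
            k = bisect_left(retained_cm, cm)
            near_left = k > 0 and cm - retained_cm[k - 1] <= radius_cm
            near_right = k < len(retained_cm) and retained_cm[k] - cm <= radius_cm
            if not (near_left or near_right):
                insort(retained_cm, cm)
                kept.append(int(i))
    return np.asarray(sorted(kept), dtype=np.intp)


def fpr_curve(null_dist: NullScanSet, lod_thresholds: np.ndarray):
    """Expected number of independent false peaks per scan at each threshold.

    Non-increasing as the threshold becomes more stringent.
    """
    import pandas as pd

    thr = np.asarray(lod_thresholds, dtype=float)
    all_peaks = (
        np.concatenate(null_dist.peak_lods) if null_dist.peak_lods else np.array([])
    )
    counts = (all_peaks[None, :] > thr[:, None]).sum(axis=1) / null_dist.n_scans
    return pd.DataFrame({"lod_threshold": thr, "expected_false_peaks": counts})


def p_to_lod(p, df: int) -> np.ndarray:
    """Nominal p-value to LOD conversion via the chi-square quantile with the
    test's degrees of freedom (1 for the dosage test, 7 for haplotypes)."""
    q = chi2.isf(np.asarray(p, dtype=float), df)
    return q / (2.0 * np.log(10.0))


@dataclass
class ThresholdSet:
    """Derived significance thresholds for one (design, sample size)."""

    design: str
    n_lines: int
    alpha: float
    genome_wide: float
    local: float
    n_scans: int

    def __post_init__(self):
        if self.local > self.genome_wide + 1e-12:
            raise ValueError("local threshold cannot exceed the genome-wide threshold")

    @classmethod
    def from_null_scans(cls, nulls: NullScanSet, alpha: float = 0.05) -> "ThresholdSet":
        return cls(
            design=nulls.design,
            n_lines=nulls.n_lines,
            alpha=alpha,
            genome_wide=fwer_threshold(nulls, alpha),
            local=local_fwer_threshold(nulls, alpha),
            n_scans=nulls.n_scans,
        )

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.__dict__, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload
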