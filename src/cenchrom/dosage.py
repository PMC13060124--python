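"""Per-chromosome, per-haplotype modification dosage and homolog balance.

CENP-A (or CENP-C / H3K9me3) dosage is proxied per chromosome and haplotype
by mean 6mA density within sub-CDRs multiplied by the aggregate sub-CDR
length. Maternal-vs-paternal concordance is summarized by the Pearson r and
the mean squared error from the identity line y = x; chromosomes whose
maternal − paternal residual has |z| > 3 (standardized against the
cross-chromosome residual mean and population SD) are flagged as outliers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from . import intervals as ivl
from .cdr import SubCdrSet
from .fiber import FiberConfig
from .io import ReadRecord


@dataclass
class HaplotypeMetrics:
    """Dosage metrics for one chromosome/haplotype."""

    chromosome: str
    haplotype: Optional[str]
    mean_density: float
    aggregate_length_bp: int
    read_coverage_bp: int  # summed read-base coverage within sub-CDRs

    @property
    def dosage_proxy(self) -> float:
        return self.mean_density * self.aggregate_length_bp


def haplotype_dosage_metrics(
    reads: Sequence[ReadRecord],
    subcdr_sets: Sequence[Union[SubCdrSet, tuple]],
    mod_type: str = "6mA",
    config: Optional[FiberConfig] = None,
) -> list[HaplotypeMetrics]:
    """Aggregate dosage metrics per chromosome/haplotype.

    Mean density pools all reads on the contig: total quality-passing calls
    within the sub-CDR intervals divided by total candidate positions there
    (so doubling read depth with identical signal leaves density unchanged).
    Entries with no overlapping read positions are omitted with a warning.
    ``read_coverage_bp``, the summed per-read base coverage of the sub-CDRs,
    is reported as a coverage-length companion metric.
    """
    config = config or FiberConfig()
    cutoff = config.min_quality(mod_type)

    by_contig: dict[str, list[ReadRecord]] = {}
    for r in reads:
        by_contig.setdefault(r.contig, []).append(r)

    out: list[HaplotypeMetrics] = []
    for entry in subcdr_sets:
        if isinstance(entry, SubCdrSet):
            contig, hap = entry.contig, entry.haplotype
            domains = entry.intervals()
        else:
            contig, domains = entry[0], list(entry[1])
            hap = None
        if not domains:
            warnings.warn(f"{contig}: no sub-CDRs; entry omitted")
            continue
        total_called = 0
        total_positions = 0
        coverage = 0
        for read in by_contig.get(contig, []):
            for d in domains:
                pos, prob = read.calls_in(mod_type, d.start, d.end)
                total_positions += int(pos.size)
                total_called += int((prob >= cutoff).sum())
                coverage += ivl.overlap_length((read.start, read.end), (d.start, d.end))
        if total_positions == 0:
            warnings.warn(f"{contig}: no overlapping reads; entry omitted")
            continue
        out.append(
            HaplotypeMetrics(
                chromosome=contig,
                haplotype=hap,
                mean_density=total_called / total_positions,
                aggregate_length_bp=int(sum(len(d) for d in domains)),
                read_coverage_bp=int(coverage),
            )
        )
    return out


@dataclass
class ConcordanceResult:
    """Maternal-vs-paternal agreement for one metric across chromosomes."""

    chromosomes: list[str]
    maternal: np.ndarray
    paternal: np.ndarray
    pearson_r: float
    mse_from_identity: float
    residuals: np.ndarray  # maternal - paternal
    z_scores: np.ndarray  # NaN when residual variance is zero
    outliers: np.ndarray  # |z| > 3

    @property
    def n_outliers(self) -> int:
        return int(self.outliers.sum())


def homolog_concordance(
    maternal: Sequence[float],
    paternal: Sequence[float],
    chromosomes: Optional[Sequence[str]] = None,
    z_cutoff: float = 3.0,
) -> ConcordanceResult:
    """Pearson r, MSE from y = x, and |z| > 3 residual outlier flags.

    Residuals (maternal − paternal) are standardized against their own mean
    and population SD. Zero residual variance leaves z undefined (NaN) and
    flags nothing.
    """
    m = np.asarray(list(maternal), dtype=float)
    p = np.asarray(list(paternal), dtype=float)
    if m.size != p.size:
        raise ValueError("maternal and paternal vectors must be paired")
    if m.size < 3:
        raise ValueError("need at least 3 chromosomes")
    if chromosomes is None:
        chromosomes = [f"chr{i+1}" for i in range(m.size)]
    r = float(stats.pearsonr(m, p).statistic) if (m.std() > 0 and p.std() > 0) else np.nan
    residuals = m - p
    mse = float(np.mean(residuals**2))
    sd = residuals.std()  # population SD (n denominator)
    if sd == 0:
        z = np.full(m.size, np.nan)
        flags = np.zeros(m.size, dtype=bool)
    else:
        z = (residuals - residuals.mean()) / sd
        flags = np.abs(z) > z_cutoff
    return ConcordanceResult(
        chromosomes=list(chromosomes),
        maternal=m,
        paternal=p,
        pearson_r=r,
        mse_from_identity=mse,
        residuals=residuals,
        z_scores=z,
        outliers=flags,
    )
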