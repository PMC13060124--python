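"""Sub-CDR architecture comparison between two cell states.

Given sub-CDR sets called in two conditions (early vs late passage, or LCL
vs iPSC), this module matches domains across conditions (any-overlap by
default, the weakest matching assumption; the overlap floor is a
parameter), derives maintained/lost/novel and expanded/contracted
bookkeeping with percent-change summaries, isolates differential regions by
per-base subtraction, normalizes densities to per-chromosome non-CDR
baselines as log2 fold-changes, runs the group statistics (Welch's t with
Cohen's d, or a paired t over chromosomes), and builds boundary-centered
aggregate metaplots.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from . import intervals as ivl
from .cdr import SubCdrSet
from .io import GenomicInterval, MethylationTrack

STATUS_EXPANDED = "expanded"
STATUS_CONTRACTED = "contracted"
STATUS_UNCHANGED = "unchanged"


def _domain_intervals(obj) -> list[GenomicInterval]:
    if isinstance(obj, SubCdrSet):
        return obj.intervals()
    return list(obj)


@dataclass
class MatchedPair:
    a_index: int
    b_indices: list[int]
    status: str
    a_length: int
    b_length: int


@dataclass
class RemodelingReport:
    """Matched comparison of two sub-CDR sets (A = reference condition)."""

    contig: str
    pairs: list[MatchedPair]
    lost: list[int]  # A-only domain indices
    novel: list[int]  # B-only domain indices
    n_a: int
    n_b: int
    lengths_a: list[int]
    lengths_b: list[int]

    @property
    def maintained(self) -> int:
        return len(self.pairs)

    @property
    def expanded(self) -> int:
        return sum(p.status == STATUS_EXPANDED for p in self.pairs)

    @property
    def contracted(self) -> int:
        return sum(p.status == STATUS_CONTRACTED for p in self.pairs)

    def counts(self) -> dict:
        return {
            "nA": self.n_a,
            "nB": self.n_b,
            "maintained": self.maintained,
            "lost": len(self.lost),
            "novel": len(self.novel),
            "expanded": self.expanded,
            "contracted": self.contracted,
        }

    def length_stats(self) -> dict:
        la, lb = self.lengths_a, self.lengths_b
        return {
            "meanA": float(np.mean(la)) if la else 0.0,
            "meanB": float(np.mean(lb)) if lb else 0.0,
            "maxA": int(max(la)) if la else 0,
            "maxB": int(max(lb)) if lb else 0,
            "totalA": int(sum(la)),
            "totalB": int(sum(lb)),
        }


def match_subcdr_sets(
    set_a: Union[SubCdrSet, Sequence[GenomicInterval]],
    set_b: Union[SubCdrSet, Sequence[GenomicInterval]],
    min_overlap_bp: int = 1,
) -> RemodelingReport:
    """Match condition-A sub-CDRs to condition-B sub-CDRs by overlap.

    An A domain is maintained iff it overlaps >= ``min_overlap_bp`` with at
    least one B domain; a maintained pair is expanded iff the summed length
    of its matched B domains exceeds the A length, contracted iff smaller.
    Many-to-one merges are recorded once on each side.
    """
    a = _domain_intervals(set_a)
    b = _domain_intervals(set_b)
    contigs = {d.contig for d in a} | {d.contig for d in b}
    if len(contigs) > 1:
        raise ValueError(f"cross-contig comparison: {sorted(contigs)}")
    contig = contigs.pop() if contigs else ""

    pairs: list[MatchedPair] = []
    lost: list[int] = []
    matched_b: set[int] = set()
    for i, da in enumerate(a):
        hits = [
            j
            for j, db in enumerate(b)
            if ivl.overlap_length(da, db) >= min_overlap_bp
        ]
        if not hits:
            lost.append(i)
            continue
        matched_b.update(hits)
        b_len = sum(len(b[j]) for j in hits)
        if b_len > len(da):
            status = STATUS_EXPANDED
        elif b_len < len(da):
            status = STATUS_CONTRACTED
        else:
            status = STATUS_UNCHANGED
        pairs.append(MatchedPair(i, hits, status, len(da), b_len))

    novel = [j for j in range(len(b)) if j not in matched_b]
    return RemodelingReport(
        contig=contig,
        pairs=pairs,
        lost=lost,
        novel=novel,
        n_a=len(a),
        n_b=len(b),
        lengths_a=[len(d) for d in a],
        lengths_b=[len(d) for d in b],
    )


def differential_regions(
    set_a: Union[SubCdrSet, Sequence[GenomicInterval]],
    set_b: Union[SubCdrSet, Sequence[GenomicInterval]],
) -> list[GenomicInterval]:
    """Per-base set difference A \\ B (regions lost from condition A)."""
    a = _domain_intervals(set_a)
    b = _domain_intervals(set_b)
    contigs = {d.contig for d in a} | {d.contig for d in b}
    if len(contigs) > 1:
        raise ValueError(f"cross-contig comparison: {sorted(contigs)}")
    if not a:
        return []
    contig = a[0].contig
    diff = ivl.subtract([(d.start, d.end) for d in a], [(d.start, d.end) for d in b])
    return [GenomicInterval(contig, s, e, name="differential") for s, e in diff]


def remodeling_summary(
    counts: Union[RemodelingReport, dict],
    lengths: Optional[dict] = None,
) -> dict:
    """Percent-change bookkeeping from matched counts.

    Accepts either a RemodelingReport or a plain counts dict (keys nA, nB,
    maintained, expanded and optionally totalA/totalB in ``lengths``).
    Percentages are unrounded; use :func:`display_round` for reporting.
    Undefined ratios (zero denominators) are returned as None.
    """
    if isinstance(counts, RemodelingReport):
        lengths = counts.length_stats()
        counts = counts.counts()
    n_a, n_b = counts["nA"], counts["nB"]
    maintained = counts.get("maintained")
    expanded = counts.get("expanded")
    out: dict = {}
    out["count_reduction_pct"] = 100.0 * (n_a - n_b) / n_a if n_a else None
    out["maintained_pct"] = (
        100.0 * maintained / n_a if (n_a and maintained is not None) else None
    )
    out["expanded_pct_of_maintained"] = (
        100.0 * expanded / maintained if (maintained and expanded is not None) else None
    )
    if lengths and lengths.get("totalA"):
        out["total_length_change_pct"] = (
            100.0 * (lengths["totalB"] - lengths["totalA"]) / lengths["totalA"]
        )
    else:
        out["total_length_change_pct"] = None
    return out


def display_round(summary: dict, ndigits: int = 1) -> dict:
    """Round percentages for display (internal values stay unrounded)."""
    return {
        k: (round(v, ndigits) if isinstance(v, float) else v) for k, v in summary.items()
    }


# ---------------------------------------------------------------------------
# baseline normalization and group statistics


def baseline_log2fc(
    region_values: Sequence[tuple[str, float]],
    baseline_values: Sequence[tuple[str, float]],
) -> tuple[np.ndarray, int]:
    """Per-region log2 fold-changes over chromosome-specific baselines.

    ``region_values`` and ``baseline_values`` are (chromosome, density)
    pairs; each region's density is divided by the mean baseline density of
    its chromosome. Fold-changes of zero or below are excluded prior to the
    log2 transform; the exclusion count is returned alongside.
    """
    baselines: dict[str, list[float]] = {}
    for chrom, v in baseline_values:
        baselines.setdefault(chrom, []).append(float(v))
    if not baselines:
        raise ValueError("empty baseline")
    base_mean = {c: float(np.mean(vs)) for c, vs in baselines.items()}
    for c, m in base_mean.items():
        if m <= 0:
            raise ValueError(f"non-positive baseline mean for {c}")

    log2fc: list[float] = []
    n_excluded = 0
    for chrom, v in region_values:
        if chrom not in base_mean:
            raise ValueError(f"no baseline for chromosome {chrom}")
        fc = float(v) / base_mean[chrom]
        if fc <= 0:
            n_excluded += 1
            continue
        log2fc.append(float(np.log2(fc)))
    return np.asarray(log2fc), n_excluded


@dataclass
class ComparisonStats:
    mode: str
    statistic: float
    p_value: float
    cohens_d: Optional[float]
    n_a: int
    n_b: int
    degenerate: bool = False


def group_comparison(
    values_a: Sequence[float], values_b: Sequence[float], mode: str = "welch"
) -> ComparisonStats:
    """Welch's two-sample t (default) or a paired two-tailed t.

    Cohen's d uses the pooled SD with n-1 denominators in both modes. The
    paired mode requires matched units (equal length, same order). Two
    identical constant groups give t = 0, p = 1, d = 0; a zero pooled SD
    with unequal means leaves d undefined (flagged degenerate).
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two values per group")
    var_a, var_b = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt(
        ((a.size - 1) * var_a + (b.size - 1) * var_b) / (a.size + b.size - 2)
    )
    mean_diff = a.mean() - b.mean()
    degenerate = False
    if pooled == 0:
        if mean_diff == 0:
            d = 0.0
        else:
            d = None
            degenerate = True
    else:
        d = float(mean_diff / pooled)

    if mode == "welch":
        if var_a == 0 and var_b == 0:
            t, p = (0.0, 1.0) if mean_diff == 0 else (np.inf, 0.0)
            degenerate = True if mean_diff != 0 else degenerate
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
    elif mode == "paired":
        if a.size != b.size:
            raise ValueError("paired mode requires equal n with matched units")
        diffs = a - b
        if np.all(diffs == diffs[0]):
            t, p = (0.0, 1.0) if diffs[0] == 0 else (np.inf, 0.0)
            degenerate = True if diffs[0] != 0 else degenerate
        else:
            t, p = stats.ttest_rel(a, b)
    else:
        raise ValueError("mode must be 'welch' or 'paired'")
    return ComparisonStats(mode, float(t), float(p), d, int(a.size), int(b.size), degenerate)


# ---------------------------------------------------------------------------
# boundary metaplots


@dataclass
class Boundary:
    """A CDR boundary with orientation.

    ``exterior`` gives the side of the array exterior (hypermethylated
    flank): "left" means the domain lies to the right of the position. Each
    boundary's window is flipped as needed so the hypomethylated (domain)
    side always sits to the right of the profile center.
    """

    contig: str
    position: int
    exterior: str = "left"

    def __post_init__(self) -> None:
        if self.exterior not in ("left", "right"):
            raise ValueError("exterior must be 'left' or 'right'")


def boundaries_of(subcdrs: Sequence[GenomicInterval]) -> list[Boundary]:
    """Both oriented boundaries of each sub-CDR interval."""
    out = []
    for d in subcdrs:
        out.append(Boundary(d.contig, d.start, exterior="left"))
        out.append(Boundary(d.contig, d.end, exterior="right"))
    return out


def boundary_metaplot(
    tracks: Sequence[MethylationTrack],
    boundaries: Sequence[Boundary],
    flank_bp: int = 20_000,
    bin_bp: int = 1_000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Aggregate signal profile centered on oriented CDR boundaries.

    Each boundary contributes a flank-centered window with the array
    exterior normalized to the left; the profile is the per-bin mean across
    boundaries. Bins with no data (including truncated flanks) are NaN, not
    zero. Returns (bin_offsets, profile, per-boundary matrix).
    """
    if flank_bp % bin_bp != 0:
        raise ValueError("flank_bp must be a multiple of bin_bp")
    n_bins = 2 * flank_bp // bin_bp
    by_contig = {t.contig: t for t in tracks}
    rows = np.full((len(boundaries), n_bins), np.nan)
    for i, bd in enumerate(boundaries):
        track = by_contig.get(bd.contig)
        if track is None:
            raise ValueError(f"no track for contig {bd.contig}")
        lo, hi = np.searchsorted(track.positions, [bd.position - flank_bp, bd.position + flank_bp])
        pos = track.positions[lo:hi]
        vals = track.values[lo:hi]
        offsets = pos - bd.position
        if bd.exterior == "right":
            offsets = -offsets - 1  # mirror so the exterior lies to the left
        idx = (offsets + flank_bp) // bin_bp
        for b in range(n_bins):
            sel = idx == b
            if sel.any():
                rows[i, b] = vals[sel].mean()
    profile = np.full(n_bins, np.nan)
    counts = np.sum(~np.isnan(rows), axis=0)
    has = counts > 0
    profile[has] = np.nanmean(rows[:, has], axis=0)
    offsets = (np.arange(n_bins) - n_bins // 2) * bin_bp + bin_bp // 2
    return offsets, profile, rows
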