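"""Single-molecule modification-density analysis.

Per-read 6mA/5mC densities are computed over MM/ML-style probability calls
(quality cutoffs 230/255 for 6mA and 210/255 for 5mC by default; one
analysis in the source protocol filters 5mC at 230, exposed via the config).
A decision-stump classifier learns the density threshold separating
CDR-enriched from background reads by exhaustively scanning midpoints
between consecutive pooled density values and minimizing the weighted Gini
impurity. Background windows are 5 kb non-overlapping tiles of the active
array at least 10 kb from any sub-CDR, capped at 15 per homolog.

Per-read CpG methylation matrices (reads x CpG sites, windowFrac = 0.95)
feed HDBSCAN clustering (min_cluster_size 5, min_samples 3,
cluster_selection_epsilon 0.005) with a Ward-linkage display ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cluster import HDBSCAN

from . import intervals as iv
from .io import GenomicInterval, MethylationTrack, ReadRecord

ENRICHED = "enriched"
NOT_ENRICHED = "not_enriched"


@dataclass
class FiberConfig:
    min_quality_6mA: int = 230
    min_quality_5mC: int = 210
    background_window_bp: int = 5_000
    max_background_windows_per_homolog: int = 15
    background_buffer_bp: int = 10_000
    span_fraction: float = 0.95

    def __post_init__(self) -> None:
        for q in (self.min_quality_6mA, self.min_quality_5mC):
            if not 0 <= q <= 255:
                raise ValueError("quality cutoffs must lie in [0, 255]")
        if not 0 < self.span_fraction <= 1:
            raise ValueError("span_fraction must lie in (0, 1]")

    def min_quality(self, mod_type: str) -> int:
        if mod_type == "6mA":
            return self.min_quality_6mA
        if mod_type == "5mC":
            return self.min_quality_5mC
        raise ValueError(f"unknown mod_type {mod_type!r}")


@dataclass
class RegionDensity:
    """Modification density of one read within one region."""

    read_id: str
    region_id: str
    mod_type: str
    n_called: int
    n_positions: int

    @property
    def density(self) -> float:
        return self.n_called / self.n_positions


def read_region_density(
    read: ReadRecord,
    region: GenomicInterval,
    mod_type: str,
    config: Optional[FiberConfig] = None,
) -> Optional[RegionDensity]:
    """Density = detected calls / candidate positions within the region.

    Calls below the per-mark quality cutoff count in the denominator only.
    Returns None ("excluded") when the read has no candidate positions in
    the region — an absent denominator is not a density of zero.
    """
    config = config or FiberConfig()
    cutoff = config.min_quality(mod_type)
    pos, prob = read.calls_in(mod_type, region.start, region.end)
    if pos.size == 0:
        return None
    n_called = int((prob >= cutoff).sum())
    region_id = region.name or f"{region.contig}:{region.start}-{region.end}"
    return RegionDensity(read.read_id, region_id, mod_type, n_called, int(pos.size))


def sample_background_windows(
    array: GenomicInterval,
    subcdrs: Sequence[GenomicInterval],
    config: Optional[FiberConfig] = None,
    seed: int = 0,
) -> list[GenomicInterval]:
    """Non-CDR background windows on one array.

    The complement of (sub-CDRs padded by the buffer) is tiled into
    non-overlapping full windows from each eligible segment's start; if more
    than the cap remain, a seeded uniform subsample of cap size is returned
    (sorted by position).
    """
    config = config or FiberConfig()
    w = config.background_window_bp
    padded = (
        iv.pad([(s.start, s.end) for s in subcdrs], config.background_buffer_bp, array.start, array.end)
        if subcdrs
        else []
    )
    eligible = iv.subtract([(array.start, array.end)], padded)
    candidates: list[tuple[int, int]] = []
    for seg_start, seg_end in eligible:
        n = (seg_end - seg_start) // w
        for k in range(n):
            candidates.append((seg_start + k * w, seg_start + (k + 1) * w))
    if not candidates:
        raise ValueError("no eligible background territory on the array")
    cap = config.max_background_windows_per_homolog
    if len(candidates) > cap:
        rng = np.random.default_rng(seed)
        chosen = rng.choice(len(candidates), size=cap, replace=False)
        candidates = [candidates[i] for i in sorted(chosen)]
    return [
        GenomicInterval(array.contig, s, e, name=f"background_{i}")
        for i, (s, e) in enumerate(candidates)
    ]


# ---------------------------------------------------------------------------
# Gini decision stump


@dataclass
class ThresholdModel:
    """A learned density threshold (reads above it are CDR-enriched)."""

    mod_type: str
    threshold: float
    achieved_impurity: float
    n_cdr: int
    n_background: int


def _weighted_gini(y: np.ndarray, side: np.ndarray) -> float:
    n = y.size
    total = 0.0
    for mask in (side, ~side):
        m = int(mask.sum())
        if m == 0:
            continue
        p1 = float(y[mask].sum()) / m
        total += (m / n) * (1.0 - p1 * p1 - (1.0 - p1) ** 2)
    return total


class GiniThresholdClassifier(BaseEstimator, ClassifierMixin):
    """Decision stump on a single density feature, split by weighted Gini.

    Candidate thresholds are the midpoints between consecutive distinct
    pooled density values; the threshold minimizing the weighted Gini
    impurity of the two partitions is selected (smallest threshold on ties).
    ``predict`` labels a density as class 1 (enriched) iff it is strictly
    above the threshold.
    """

    def __init__(self, mod_type: str = "6mA"):
        self.mod_type = mod_type

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y)
        if x.size != y.size or x.size == 0:
            raise ValueError("X and y must be non-empty and of equal length")
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("exactly two classes are required")
        y01 = (y == self.classes_[1]).astype(int)

        order = np.argsort(x, kind="stable")
        xs, ys = x[order], y01[order]
        distinct = np.unique(xs)
        if distinct.size < 2:
            warnings.warn("all densities identical; threshold is degenerate")
            p1 = ys.mean()
            self.threshold_ = float(distinct[0])
            self.impurity_ = float(1.0 - p1 * p1 - (1 - p1) ** 2)
            return self

        midpoints = (distinct[:-1] + distinct[1:]) / 2.0
        best_thr, best_imp = None, np.inf
        for thr in midpoints:
            imp = _weighted_gini(ys, xs <= thr)
            if imp < best_imp - 1e-15:
                best_imp, best_thr = imp, thr
        self.threshold_ = float(best_thr)
        self.impurity_ = float(best_imp)
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return np.where(x > self.threshold_, self.classes_[1], self.classes_[0])


def learn_density_threshold(
    cdr_densities: Sequence[float],
    background_densities: Sequence[float],
    mod_type: str = "6mA",
) -> ThresholdModel:
    """Learn the CDR vs background density threshold (Gini decision stump)."""
    cdr = np.asarray(list(cdr_densities), dtype=float)
    bg = np.asarray(list(background_densities), dtype=float)
    if cdr.size == 0 or bg.size == 0:
        raise ValueError("both density classes must be non-empty")
    x = np.concatenate([bg, cdr])
    y = np.concatenate([np.zeros(bg.size, int), np.ones(cdr.size, int)])
    clf = GiniThresholdClassifier(mod_type=mod_type).fit(x, y)
    return ThresholdModel(
        mod_type=mod_type,
        threshold=clf.threshold_,
        achieved_impurity=clf.impurity_,
        n_cdr=int(cdr.size),
        n_background=int(bg.size),
    )


def classify_read(density: RegionDensity, model: ThresholdModel) -> str:
    """Enriched iff density strictly above the learned threshold."""
    return ENRICHED if density.density > model.threshold else NOT_ENRICHED


# ---------------------------------------------------------------------------
# co-occupancy


@dataclass
class CooccupancySummary:
    n_reads: int
    n_overlapping: int
    n_spanning_2plus: int
    n_mcpg_depleted_all: int
    n_cenpa_multi: int

    @property
    def frac_mcpg_depleted_all(self) -> Optional[float]:
        return self.n_mcpg_depleted_all / self.n_spanning_2plus if self.n_spanning_2plus else None

    @property
    def frac_cenpa_multi(self) -> Optional[float]:
        return self.n_cenpa_multi / self.n_spanning_2plus if self.n_spanning_2plus else None


def cooccupancy_analysis(
    reads: Sequence[ReadRecord],
    subcdrs: Sequence[GenomicInterval],
    cenpa_model: ThresholdModel,
    mcpg_model: ThresholdModel,
    config: Optional[FiberConfig] = None,
) -> CooccupancySummary:
    """Single-molecule co-occupancy across sub-CDRs.

    A read "fully spans" a sub-CDR when its alignment covers at least
    ``span_fraction`` of it. Over reads fully spanning >= 2 sub-CDRs we
    count: molecules mCpG-depleted (5mC density strictly below the 5mC
    threshold) at every spanned sub-CDR, and molecules CENP-A-positive (6mA
    density strictly above the 6mA threshold) at two or more spanned
    sub-CDRs.
    """
    config = config or FiberConfig()
    n_overlapping = 0
    n_spanning = 0
    n_depleted_all = 0
    n_cenpa_multi = 0
    for read in reads:
        spanned = []
        overlaps = False
        for sc in subcdrs:
            ov = iv.overlap_length((read.start, read.end), (sc.start, sc.end))
            if ov > 0:
                overlaps = True
            if ov >= config.span_fraction * len(sc):
                spanned.append(sc)
        if overlaps:
            n_overlapping += 1
        if len(spanned) < 2:
            continue
        n_spanning += 1
        depleted = []
        cenpa_pos = 0
        for sc in spanned:
            d5 = read_region_density(read, sc, "5mC", config)
            depleted.append(d5 is not None and d5.density < mcpg_model.threshold)
            d6 = read_region_density(read, sc, "6mA", config)
            if d6 is not None and d6.density > cenpa_model.threshold:
                cenpa_pos += 1
        if all(depleted):
            n_depleted_all += 1
        if cenpa_pos >= 2:
            n_cenpa_multi += 1
    return CooccupancySummary(
        n_reads=len(reads),
        n_overlapping=n_overlapping,
        n_spanning_2plus=n_spanning,
        n_mcpg_depleted_all=n_depleted_all,
        n_cenpa_multi=n_cenpa_multi,
    )


# ---------------------------------------------------------------------------
# per-read methylation matrices and clustering


def build_methylation_matrix(
    reads: Sequence[ReadRecord],
    region: GenomicInterval,
    track: MethylationTrack,
    config: Optional[FiberConfig] = None,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Reads x CpG-sites matrix of 5mC probabilities in [0, 1].

    Columns are the track's reference CpG positions within the region; rows
    are reads covering >= span_fraction of the region. Entries with no call
    on a read are NaN (missing), not zero.
    """
    config = config or FiberConfig()
    region_track = track.slice(region.start, region.end)
    cols = region_track.positions
    if cols.size == 0:
        raise ValueError("region contains no CpG sites")
    retained = [
        r
        for r in reads
        if iv.overlap_length((r.start, r.end), (region.start, region.end))
        >= config.span_fraction * len(region)
    ]
    if not retained:
        raise ValueError("no reads span the region at the required fraction")
    matrix = np.full((len(retained), cols.size), np.nan)
    for i, read in enumerate(retained):
        pos, prob = read.calls_in("5mC", region.start, region.end)
        idx = np.searchsorted(cols, pos)
        hit = (idx < cols.size) & (cols[np.minimum(idx, cols.size - 1)] == pos)
        matrix[i, idx[hit]] = prob[hit] / 255.0
    return matrix, [r.read_id for r in retained], cols


@dataclass
class ClusterParams:
    min_cluster_size: int = 5
    min_samples: int = 3
    cluster_selection_epsilon: float = 0.005


class MethylationReadClusterer(BaseEstimator):
    """HDBSCAN over per-read methylation rows, with Ward display ordering.

    Missing entries are mean-imputed per column for distance computation
    only. Noise rows receive label -1 and are excluded from summaries.
    Fitted attributes: ``labels_``, ``ordering_`` (Ward-linkage leaf order).
    """

    def __init__(
        self,
        min_cluster_size: int = 5,
        min_samples: int = 3,
        cluster_selection_epsilon: float = 0.005,
    ):
        self.min_cluster_size = min_cluster_size
        self.min_samples = min_samples
        self.cluster_selection_epsilon = cluster_selection_epsilon

    def fit(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("matrix must be 2-D (reads x CpG sites)")
        filled = X.copy()
        col_means = np.nanmean(np.where(np.isnan(filled), np.nan, filled), axis=0)
        col_means = np.where(np.isfinite(col_means), col_means, 0.5)
        nan_mask = np.isnan(filled)
        filled[nan_mask] = np.take(col_means, np.nonzero(nan_mask)[1])
        self.imputed_ = filled

        n = X.shape[0]
        if n < self.min_cluster_size:
            warnings.warn(
                f"{n} reads < min_cluster_size {self.min_cluster_size}; all labeled noise"
            )
            self.labels_ = np.full(n, -1, dtype=int)
        elif np.all(filled == filled[0]):
            # identical rows: density estimation degenerates; one cluster
            self.labels_ = np.zeros(n, dtype=int)
        else:
            h = HDBSCAN(
                min_cluster_size=self.min_cluster_size,
                min_samples=self.min_samples,
                cluster_selection_epsilon=self.cluster_selection_epsilon,
                copy=True,
            )
            self.labels_ = h.fit(filled).labels_.astype(int)
        if n >= 2:
            Z = linkage(filled, method="ward")
            self.ordering_ = leaves_list(Z).astype(int)
        else:
            self.ordering_ = np.arange(n)
        return self

    def fit_predict(self, X) -> np.ndarray:
        return self.fit(X).labels_


def cluster_methylation_matrix(
    matrix: np.ndarray, params: Optional[ClusterParams] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster a reads x CpG matrix; returns (labels, display ordering)."""
    params = params or ClusterParams()
    clusterer = MethylationReadClusterer(
        min_cluster_size=params.min_cluster_size,
        min_samples=params.min_samples,
        cluster_selection_epsilon=params.cluster_selection_epsilon,
    ).fit(matrix)
    return clusterer.labels_, clusterer.ordering_
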