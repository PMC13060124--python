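"""Synthetic-study evaluation harness.

Seeded experiments that measure the pipeline against the generator's planted
ground truth: sub-CDR recovery (recall/precision/boundary error), read
classification accuracy at the stated 6mA contrast, Ward clade recovery,
condition-pair remodeling label agreement, homolog-outlier calibration on
balanced haplotypes, and the uniformity of the homogeneity permutation
p-value under a random-placement null.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .cdr import CdrCallerConfig, call_subcdrs
from .dosage import homolog_concordance
from .fiber import (
    FiberConfig,
    cooccupancy_analysis,
    learn_density_threshold,
    read_region_density,
    sample_background_windows,
)
from .horhap import (
    IdentityTrack,
    WardCladeClusterer,
    cdr_homogeneity_permutation,
    neighbor_average_identity,
)
from .io import GenomicInterval
from .remodeling import match_subcdr_sets
from .synthetic import (
    ArraySpec,
    HorArraySpec,
    PlantedDomain,
    ReadModel,
    RemodelSpec,
    generate_condition_pair,
    generate_hor_units,
    generate_methylation_track,
    generate_read_set,
    random_domain_layout,
)


def _sub_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def cdr_recovery_experiment(n_arrays: int = 50, seed: int = 0) -> dict:
    """Recall/precision of high-confidence calls against planted sub-CDRs.

    Each array carries 2–9 planted LCL-like dips (16–40 kb, depths bringing
    ~60% baseline to 10–25%, per-CpG noise SD 10 pp). A planted domain is
    recovered when a high-confidence call overlaps it; boundary error is the
    larger start/end offset of the overlapping call.
    """
    rng = np.random.default_rng(seed)
    config = CdrCallerConfig()
    n_planted = n_called = n_recovered = n_called_matched = 0
    boundary_errors: list[int] = []
    for _ in range(n_arrays):
        spec = ArraySpec(length_bp=1_000_000)
        domains = random_domain_layout(spec, rng)
        track = generate_methylation_track(spec, domains, seed=_sub_seed(rng))
        called = [
            d.interval
            for d in call_subcdrs(track, config=config).domains
            if d.tier == "high_confidence"
        ]
        n_planted += len(domains)
        n_called += len(called)
        for dom in domains:
            hits = [c for c in called if c.start < dom.end and c.end > dom.start]
            if hits:
                n_recovered += 1
                best = max(hits, key=lambda c: min(c.end, dom.end) - max(c.start, dom.start))
                boundary_errors.append(
                    max(abs(best.start - dom.start), abs(best.end - dom.end))
                )
        for c in called:
            if any(c.start < dom.end and c.end > dom.start for dom in domains):
                n_called_matched += 1
    return {
        "n_arrays": n_arrays,
        "n_planted": n_planted,
        "n_called": n_called,
        "recall": n_recovered / n_planted,
        "precision": n_called_matched / n_called if n_called else float("nan"),
        "max_boundary_error_bp": int(max(boundary_errors)) if boundary_errors else 0,
        "boundary_tolerance_bp": config.window_bp // 2 + config.step_bp,
    }


def classifier_accuracy_experiment(
    seed: int = 0, n_reads: int = 500, model: Optional[ReadModel] = None
) -> dict:
    """Accuracy of the learned 6mA threshold at the stated signal contrast.

    Reads are simulated at the default in-domain vs background detection
    contrast (0.2 vs 0.005); the stump is trained on one read set and
    evaluated on per-(read, region) densities from an independently seeded
    one, labeling sub-CDR regions enriched and background windows not.
    """
    rng = np.random.default_rng(seed)
    model = model or ReadModel()
    spec = ArraySpec(length_bp=600_000)
    domains = random_domain_layout(spec, rng, n_domains=3)
    track = generate_methylation_track(spec, domains, seed=_sub_seed(rng))
    regions = [GenomicInterval(spec.contig_name, d.start, d.end) for d in domains]
    bg = sample_background_windows(spec.interval(), regions, seed=_sub_seed(rng))

    def densities(reads):
        cdr_d, bg_d = [], []
        for read in reads:
            for region in regions:
                d = read_region_density(read, region, "6mA")
                if d is not None:
                    cdr_d.append(d.density)
            for region in bg:
                d = read_region_density(read, region, "6mA")
                if d is not None:
                    bg_d.append(d.density)
        return cdr_d, bg_d

    train = generate_read_set(track, domains, model, n_reads, seed=_sub_seed(rng))
    test = generate_read_set(track, domains, model, n_reads, seed=_sub_seed(rng))
    threshold_model = learn_density_threshold(*densities(train))
    cdr_d, bg_d = densities(test)
    correct = sum(d > threshold_model.threshold for d in cdr_d) + sum(
        d <= threshold_model.threshold for d in bg_d
    )
    total = len(cdr_d) + len(bg_d)
    return {
        "threshold": threshold_model.threshold,
        "impurity": threshold_model.achieved_impurity,
        "n_test_regions": total,
        "accuracy": correct / total,
    }


def cooccupancy_experiment(seed: int = 0, n_reads: int = 300) -> dict:
    """Multi-domain CENP-A co-occupancy on ultra-long synthetic molecules."""
    rng = np.random.default_rng(seed)
    spec = ArraySpec(length_bp=600_000)
    domains = random_domain_layout(spec, rng, n_domains=3)
    track = generate_methylation_track(spec, domains, seed=_sub_seed(rng))
    regions = [GenomicInterval(spec.contig_name, d.start, d.end) for d in domains]
    model = ReadModel(read_length_mean_bp=200_000, read_length_sd_bp=40_000)
    reads = generate_read_set(track, domains, model, n_reads, seed=_sub_seed(rng))
    bg = sample_background_windows(spec.interval(), regions, seed=_sub_seed(rng))

    cdr6, bg6, cdr5, bg5 = [], [], [], []
    for read in reads:
        for region in regions:
            d6 = read_region_density(read, region, "6mA")
            if d6 is not None:
                cdr6.append(d6.density)
            d5 = read_region_density(read, region, "5mC")
            if d5 is not None:
                cdr5.append(d5.density)
        for region in bg:
            d6 = read_region_density(read, region, "6mA")
            if d6 is not None:
                bg6.append(d6.density)
            d5 = read_region_density(read, region, "5mC")
            if d5 is not None:
                bg5.append(d5.density)
    cenpa_model = learn_density_threshold(cdr6, bg6, "6mA")
    mcpg_model = learn_density_threshold(bg5, cdr5, "5mC")  # enriched side = background
    summary = cooccupancy_analysis(reads, regions, cenpa_model, mcpg_model)
    return {
        "n_spanning": summary.n_spanning_2plus,
        "frac_mcpg_depleted_all": summary.frac_mcpg_depleted_all,
        "frac_cenpa_multi": summary.frac_cenpa_multi,
        "cenpa_threshold": cenpa_model.threshold,
        "mcpg_threshold": mcpg_model.threshold,
    }


def clade_recovery_experiment(n_trials: int = 100, seed: int = 0) -> dict:
    """Ward clade recovery at >= 5x between/within divergence separation."""
    rng = np.random.default_rng(seed)
    aris = []
    for _ in range(n_trials):
        k = int(rng.integers(2, 4))
        spec = HorArraySpec(
            n_units=int(rng.integers(18, 36)),
            unit_length=120,
            n_clades=k,
            variants_per_clade=10,
        )
        units, truth = generate_hor_units(spec, mutation_rate=0.005, seed=_sub_seed(rng))
        labels = WardCladeClusterer(n_clades=k).fit_predict(units)
        aris.append(adjusted_rand_score(truth, labels))
    return {"n_trials": n_trials, "min_ari": float(min(aris)), "mean_ari": float(np.mean(aris))}


def condition_pair_label_experiment(seed: int = 0) -> dict:
    """Do matcher labels reproduce the condition-pair generator's truth?"""
    spec = ArraySpec(length_bp=1_000_000)
    domains = [
        PlantedDomain(100_000 + 90_000 * i, 130_000 + 90_000 * i) for i in range(6)
    ]
    remodel = RemodelSpec(
        merge_gaps=[2],
        boundary_shifts={0: (-5_000, 3_000), 4: (4_000, -6_000)},
        lost=[5],
        novel=[PlantedDomain(820_000, 850_000)],
    )
    pair = generate_condition_pair(spec, domains, remodel, seed=seed)
    a = [GenomicInterval(spec.contig_name, d.start, d.end) for d in pair.domains_a]
    b = [GenomicInterval(spec.contig_name, d.start, d.end) for d in pair.domains_b]
    report = match_subcdr_sets(a, b)
    called = {i: "lost" for i in report.lost}
    for p in report.pairs:
        called[p.a_index] = "maintained" if p.status == "unchanged" else p.status
    return {
        "n_domains": len(domains),
        "labels_match": called == pair.statuses and len(report.novel) == len(pair.novel),
    }


def homolog_outlier_calibration(n_seeds: int = 100, seed: int = 0, n_chrom: int = 24) -> dict:
    """Outlier rate at |z| > 3 on balanced homologs with sampling noise only."""
    rng = np.random.default_rng(seed)
    n_positions = 5_000
    flags = 0
    for _ in range(n_seeds):
        true_density = rng.uniform(0.01, 0.03, size=n_chrom)
        maternal = rng.binomial(n_positions, true_density) / n_positions
        paternal = rng.binomial(n_positions, true_density) / n_positions
        flags += homolog_concordance(maternal, paternal).n_outliers
    return {
        "n_seeds": n_seeds,
        "n_chromosomes": n_chrom,
        "outlier_rate": flags / (n_seeds * n_chrom),
    }


def permutation_null_uniformity(
    n_reps: int = 500, n_perm: int = 199, seed: int = 0
) -> dict:
    """p-value distribution when CDRs are placed at random (null is true)."""
    from scipy import stats

    rng = np.random.default_rng(seed)
    window = 5_000
    n_windows = 100
    array = GenomicInterval("chrT", 0, n_windows * window)
    pvals = []
    for _ in range(n_reps):
        starts = np.arange(n_windows) * window
        track = neighbor_average_identity(
            IdentityTrack("chrT", starts, starts + window, rng.uniform(85, 100, n_windows))
        )
        length = int(rng.integers(20_000, 60_000))
        start = int(rng.integers(0, array.end - length))
        cdr = GenomicInterval("chrT", start, start + length)
        res = cdr_homogeneity_permutation(
            [cdr], track, array, n_perm=n_perm, seed=_sub_seed(rng)
        )
        pvals.append(res["p_value"])
    pvals = np.asarray(pvals)
    ks = stats.kstest(pvals, "uniform")
    return {
        "n_reps": n_reps,
        "ks_statistic": float(ks.statistic),
        "ks_p_value": float(ks.pvalue),
        "mean_p": float(pvals.mean()),
    }
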