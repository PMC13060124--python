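"""Synthetic centromere data with known planted structure.

Every downstream stage of the pipeline is exercised on data from this module:
methylation tracks with planted hypomethylated sub-CDR dips, ultra-long read
sets with MM/ML-style 6mA/5mC probability calls, matched condition pairs with
ground-truth remodeling labels, and aligned HOR unit sets with planted clade
variants and superHOR periodicity.

Default parameters emulate the study system: LCL-like arrays at ~60% baseline
mCpG with sub-CDR dips down to 10–25%, iPSC-like arrays at ~90% baseline with
shallow dips to ~60%, 2–9 sub-CDRs of ~16–40 kb per array, and reads on a
tens-of-kb length scale. Coordinates are 0-based half-open throughout. All
generators are pure functions of (spec, seed): the same inputs always yield
identical outputs.

CpG positions are drawn as a jittered lattice rather than from sequence
(nucleotide context is never needed downstream), and adenine-proxy positions
for 6mA sit on a fixed lattice (default one per 4 bp).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import GenomicInterval, MethylationTrack, ReadRecord


@dataclass
class ArraySpec:
    """One active alpha-satellite array to simulate.

    ``baseline_methylation_pct`` and ``noise_sd_pct`` set the array-wide CpG
    methylation level and its per-CpG scatter; LCL-like arrays sit near 60%
    and iPSC-like arrays near 90%.
    """

    contig_name: str = "chrS_MATERNAL"
    length_bp: int = 1_000_000
    cpg_spacing_bp: float = 25.0
    baseline_methylation_pct: float = 60.0
    noise_sd_pct: float = 10.0

    def __post_init__(self) -> None:
        if self.length_bp <= 0 or self.cpg_spacing_bp <= 0:
            raise ValueError("length_bp and cpg_spacing_bp must be positive")
        if not 0 <= self.baseline_methylation_pct <= 100:
            raise ValueError("baseline_methylation_pct must lie in [0, 100]")
        if self.noise_sd_pct < 0:
            raise ValueError("noise_sd_pct must be non-negative")

    @property
    def haplotype(self) -> Optional[str]:
        from .io import parse_haplotype

        return parse_haplotype(self.contig_name)

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.contig_name, 0, self.length_bp, name="active_array")


def ipsc_array_spec(**overrides) -> ArraySpec:
    """iPSC-like preset: ~90% baseline with shallow dips (pair with depth ~30)."""
    defaults = dict(baseline_methylation_pct=90.0, noise_sd_pct=8.0)
    defaults.update(overrides)
    return ArraySpec(**defaults)


@dataclass
class PlantedDomain:
    """A planted hypomethylated sub-CDR, optionally CENP-A / H3K9me3 marked."""

    start: int
    end: int
    dip_depth_pct: float = 40.0
    cenpa_enriched: bool = True
    h3k9me3_enriched: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("planted domain start must be < end")
        if not 0 < self.dip_depth_pct <= 100:
            raise ValueError("dip_depth_pct must lie in (0, 100]")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ReadModel:
    """Read-length and modification-call model for simulated molecules.

    6mA probabilities contrast CENP-A-marked planted domains against
    background: a candidate adenine-proxy position is "detected" (probability
    drawn near ``quality_high``) with chance ``prob_6ma_in_domain`` inside a
    CENP-A domain and ``prob_6ma_background`` outside. 5mC detection follows
    the methylation track: each CpG on a molecule is methylated with chance
    track_value/100.
    """

    read_length_mean_bp: float = 50_000.0
    read_length_sd_bp: float = 15_000.0
    min_read_length_bp: int = 1_000
    prob_6ma_in_domain: float = 0.2
    prob_6ma_background: float = 0.005
    quality_high: int = 250
    quality_low: int = 20
    adenine_spacing_bp: int = 4

    def __post_init__(self) -> None:
        if self.read_length_mean_bp <= 0 or self.read_length_sd_bp < 0:
            raise ValueError("read length parameters must be positive")
        for p in (self.prob_6ma_in_domain, self.prob_6ma_background):
            if not 0 <= p <= 1:
                raise ValueError("modification call probabilities must lie in [0, 1]")
        for q in (self.quality_high, self.quality_low):
            if not 0 <= q <= 255:
                raise ValueError("quality values must lie in [0, 255]")


def _validate_domains(spec: ArraySpec, domains: Sequence[PlantedDomain]) -> list[PlantedDomain]:
    domains = sorted(domains, key=lambda d: d.start)
    for d in domains:
        if d.start < 0 or d.end > spec.length_bp:
            raise ValueError(f"planted domain [{d.start}, {d.end}) outside array bounds")
        if spec.baseline_methylation_pct - d.dip_depth_pct < 0:
            raise ValueError("dip depth exceeds baseline methylation")
    for a, b in zip(domains, domains[1:]):
        if b.start < a.end:
            raise ValueError(
                f"planted domains overlap: [{a.start},{a.end}) and [{b.start},{b.end})"
            )
    return domains


def generate_methylation_track(
    spec: ArraySpec, domains: Sequence[PlantedDomain], seed: int = 0
) -> MethylationTrack:
    """Per-CpG methylation with planted dips plus Gaussian noise.

    CpG positions are a jittered lattice at ``cpg_spacing_bp``; values are
    baseline − dip depth inside planted domains, plus N(0, noise_sd), clamped
    to [0, 100].
    """
    domains = _validate_domains(spec, domains)
    rng = np.random.default_rng(seed)
    n = int(spec.length_bp / spec.cpg_spacing_bp)
    lattice = (np.arange(n) + 0.5) * spec.cpg_spacing_bp
    jitter = rng.uniform(-0.45, 0.45, size=n) * spec.cpg_spacing_bp
    positions = np.unique(np.clip(np.round(lattice + jitter), 0, spec.length_bp - 1).astype(np.int64))

    values = np.full(positions.size, spec.baseline_methylation_pct, dtype=float)
    for d in domains:
        inside = (positions >= d.start) & (positions < d.end)
        values[inside] -= d.dip_depth_pct
    if spec.noise_sd_pct > 0:
        values += rng.normal(0.0, spec.noise_sd_pct, size=positions.size)
    np.clip(values, 0.0, 100.0, out=values)
    return MethylationTrack(spec.contig_name, positions, values)


def generate_read_set(
    track: MethylationTrack,
    domains: Sequence[PlantedDomain],
    model: ReadModel,
    n_reads: int,
    seed: int = 0,
    array_length: Optional[int] = None,
) -> list[ReadRecord]:
    """Simulate ultra-long reads with 6mA and 5mC probability calls.

    Read spans are sampled over the array; 6mA calls sit on the fixed
    adenine-proxy lattice with in-domain vs background contrast per the
    model; 5mC calls sit on the track's CpGs with per-molecule Bernoulli
    methylation at the local track value.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if array_length is None:
        array_length = int(track.positions[-1]) + 1 if len(track) else 0
    cenpa = [(d.start, d.end) for d in domains if d.cenpa_enriched]
    rng = np.random.default_rng(seed)

    lengths = rng.normal(model.read_length_mean_bp, model.read_length_sd_bp, size=n_reads)
    lengths = np.clip(np.round(lengths), model.min_read_length_bp, array_length).astype(np.int64)
    starts = rng.integers(0, np.maximum(1, array_length - lengths), size=n_reads)
    ends = starts + lengths

    reads: list[ReadRecord] = []
    spacing = model.adenine_spacing_bp
    for i in range(n_reads):
        start, end = int(starts[i]), int(ends[i])
        # 6mA on the global adenine-proxy lattice within the span
        first = -(-start // spacing) * spacing
        apos = np.arange(first, end, spacing, dtype=np.int64)
        in_domain = np.zeros(apos.size, dtype=bool)
        for ds, de in cenpa:
            in_domain |= (apos >= ds) & (apos < de)
        p_call = np.where(in_domain, model.prob_6ma_in_domain, model.prob_6ma_background)
        detected = rng.random(apos.size) < p_call
        aprob = np.where(detected, model.quality_high, model.quality_low).astype(np.int64)

        # 5mC at the track's CpGs within the span, Bernoulli at the track value
        lo, hi = np.searchsorted(track.positions, [start, end])
        cpos = track.positions[lo:hi]
        methylated = rng.random(cpos.size) < (track.values[lo:hi] / 100.0)
        cprob = np.where(methylated, model.quality_high, model.quality_low).astype(np.int64)

        reads.append(
            ReadRecord(
                read_id=f"read_{i:05d}",
                contig=track.contig,
                start=start,
                end=end,
                calls={"6mA": (apos, aprob), "5mC": (cpos.copy(), cprob)},
                haplotype=track.haplotype,
            )
        )
    return reads


# ---------------------------------------------------------------------------
# condition pairs


@dataclass
class RemodelSpec:
    """Edits turning condition A's planted domains into condition B's.

    * ``merge_gaps`` — indices i meaning: de-methylate the gap between
      domain i and domain i+1, merging them into one larger domain.
    * ``boundary_shifts`` — map domain index -> (start_shift, end_shift) in
      bp (negative start shift / positive end shift expand the domain).
    * ``lost`` — indices of A domains absent in B.
    * ``novel`` — new PlantedDomains present only in B.
    """

    merge_gaps: Sequence[int] = ()
    boundary_shifts: dict = field(default_factory=dict)
    lost: Sequence[int] = ()
    novel: Sequence[PlantedDomain] = ()


@dataclass
class ConditionPair:
    """Two (track, domains) conditions plus per-domain ground-truth labels.

    ``statuses`` maps each condition-A domain index to "maintained",
    "expanded", "contracted", or "lost"; merged A domains are all labeled
    "expanded" (they match one larger B domain). ``novel`` lists B-only
    domains.
    """

    track_a: MethylationTrack
    domains_a: list[PlantedDomain]
    track_b: MethylationTrack
    domains_b: list[PlantedDomain]
    statuses: dict
    novel: list[PlantedDomain]


def generate_condition_pair(
    spec: ArraySpec,
    domains: Sequence[PlantedDomain],
    remodel: RemodelSpec,
    seed: int = 0,
    spec_b: Optional[ArraySpec] = None,
) -> ConditionPair:
    """Condition A plus a remodeled condition B with ground-truth labels."""
    domains = _validate_domains(spec, domains)
    n = len(domains)
    for idx in list(remodel.merge_gaps) + list(remodel.lost) + list(remodel.boundary_shifts):
        if not 0 <= idx < n:
            raise ValueError(f"remodel edit references domain index {idx} out of range")

    lost = set(remodel.lost)
    merged_into: dict[int, int] = {}  # A index -> merge-group leader
    for i in remodel.merge_gaps:
        if i + 1 >= n:
            raise ValueError("merge_gaps index must have a right neighbour")
        if i in lost or i + 1 in lost:
            raise ValueError("cannot merge a lost domain")
        leader = merged_into.get(i, i)
        merged_into[i] = leader
        merged_into[i + 1] = leader

    # build B domains group by group
    statuses: dict[int, str] = {}
    b_domains: list[PlantedDomain] = []
    group_members: dict[int, list[int]] = {}
    for i in range(n):
        if i in lost:
            statuses[i] = "lost"
            continue
        leader = merged_into.get(i, i)
        group_members.setdefault(leader, []).append(i)

    for leader, members in group_members.items():
        start = min(domains[i].start for i in members)
        end = max(domains[i].end for i in members)
        s_shift, e_shift = 0, 0
        for i in members:
            if i in remodel.boundary_shifts:
                si, ei = remodel.boundary_shifts[i]
                s_shift += si
                e_shift += ei
        new_start = max(0, start + s_shift)
        new_end = min(spec.length_bp, end + e_shift)
        depth = float(np.mean([domains[i].dip_depth_pct for i in members]))
        b_domains.append(
            PlantedDomain(
                new_start,
                new_end,
                depth,
                cenpa_enriched=any(domains[i].cenpa_enriched for i in members),
                h3k9me3_enriched=any(domains[i].h3k9me3_enriched for i in members),
            )
        )
        new_len = new_end - new_start
        for i in members:
            if len(members) > 1:
                statuses[i] = "expanded"
            elif new_len > len(domains[i]):
                statuses[i] = "expanded"
            elif new_len < len(domains[i]):
                statuses[i] = "contracted"
            else:
                statuses[i] = "maintained"

    b_domains.extend(remodel.novel)
    b_domains = _validate_domains(spec_b or spec, b_domains)

    track_a = generate_methylation_track(spec, domains, seed)
    track_b = generate_methylation_track(spec_b or spec, b_domains, seed + 1)
    return ConditionPair(track_a, list(domains), track_b, b_domains, statuses, list(remodel.novel))


# ---------------------------------------------------------------------------
# HOR arrays


@dataclass
class HorArraySpec:
    """An array of equal-length aligned HOR units with planted clades.

    Clade 0's ancestor is the root sequence; every other clade's ancestor
    differs from the root at ``variants_per_clade`` private columns, so any
    two distinct clades c > 0 differ at 2 x variants_per_clade columns and
    clade 0 differs from clade c at variants_per_clade columns.
    """

    n_units: int = 60
    unit_length: int = 120
    n_clades: int = 2
    variants_per_clade: int = 5
    clade_layout: Optional[Sequence[int]] = None
    superhor_pattern: Optional[tuple[Sequence[int], int]] = None

    def __post_init__(self) -> None:
        if self.n_units <= 0 or self.unit_length <= 0:
            raise ValueError("n_units and unit_length must be positive")
        if self.n_clades < 1 or self.variants_per_clade <= 0:
            raise ValueError("n_clades must be >= 1, variants_per_clade positive")
        if self.n_clades * self.variants_per_clade > self.unit_length:
            raise ValueError("variants_per_clade x n_clades must not exceed unit_length")
        if self.superhor_pattern is not None and self.clade_layout is None:
            pattern, repeats = self.superhor_pattern
            layout = list(pattern) * repeats
            if len(layout) > self.n_units:
                raise ValueError("superhor pattern longer than n_units")
            # pad the remainder with a block of clade 0
            layout += [0] * (self.n_units - len(layout))
            self.clade_layout = layout
        if self.clade_layout is None:
            # contiguous blocks of equal size, one per clade
            per = self.n_units // self.n_clades
            layout = []
            for c in range(self.n_clades):
                layout += [c] * per
            layout += [self.n_clades - 1] * (self.n_units - len(layout))
            self.clade_layout = layout
        if len(self.clade_layout) != self.n_units:
            raise ValueError("clade_layout length must equal n_units")
        if any(not 0 <= c < self.n_clades for c in self.clade_layout):
            raise ValueError("clade ids in layout must be < n_clades")


@dataclass
class HorUnit:
    """One aligned HOR repeat unit (equal-length gapped sequence)."""

    index: int
    sequence: str
    stv_label: Optional[str] = None


_BASES = np.array(list("ACGT"))


def generate_hor_units(
    spec: HorArraySpec, mutation_rate: float = 0.01, seed: int = 0
) -> tuple[list[HorUnit], np.ndarray]:
    """Aligned HOR units drawn from planted clade ancestors.

    Returns (units, true_clade_labels). Each unit is its clade's ancestral
    sequence with random substitutions at ``mutation_rate`` per column.
    """
    if not 0 <= mutation_rate < 0.5:
        raise ValueError("mutation_rate must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    L = spec.unit_length
    root = rng.integers(0, 4, size=L)

    variant_cols = rng.choice(L, size=spec.n_clades * spec.variants_per_clade, replace=False)
    ancestors = np.tile(root, (spec.n_clades, 1))
    for c in range(1, spec.n_clades):
        cols = variant_cols[c * spec.variants_per_clade : (c + 1) * spec.variants_per_clade]
        ancestors[c, cols] = (ancestors[c, cols] + rng.integers(1, 4, size=cols.size)) % 4

    labels = np.asarray(spec.clade_layout, dtype=int)
    units: list[HorUnit] = []
    for i, c in enumerate(labels):
        seq = ancestors[c].copy()
        if mutation_rate > 0:
            mutate = rng.random(L) < mutation_rate
            seq[mutate] = (seq[mutate] + rng.integers(1, 4, size=int(mutate.sum()))) % 4
        units.append(HorUnit(index=i, sequence="".join(_BASES[seq])))
    return units, labels


# ---------------------------------------------------------------------------
# batch scenario helper


def random_domain_layout(
    spec: ArraySpec,
    rng: np.random.Generator,
    n_domains: Optional[int] = None,
    length_range: tuple[int, int] = (16_000, 40_000),
    depth_range: tuple[float, float] = (35.0, 50.0),
    min_gap_bp: int = 40_000,
    edge_margin_bp: int = 50_000,
) -> list[PlantedDomain]:
    """Randomly place 2–9 non-overlapping sub-CDR dips on an array.

    Defaults mirror the study's observed sub-CDR geometry: 2–9 domains of
    16–40 kb separated by methylated gaps, with LCL dip depths bringing
    ~60% baseline down to 10–25%.
    """
    if n_domains is None:
        n_domains = int(rng.integers(2, 10))
    for _ in range(1000):
        lengths = rng.integers(length_range[0], length_range[1] + 1, size=n_domains)
        usable = spec.length_bp - 2 * edge_margin_bp
        slack = usable - int(lengths.sum()) - min_gap_bp * (n_domains - 1)
        if slack <= 0:
            n_domains -= 1
            if n_domains < 2:
                raise ValueError("array too short for requested domain layout")
            continue
        cuts = np.sort(rng.uniform(0, slack, size=n_domains))
        starts = edge_margin_bp + cuts + np.concatenate(
            ([0], np.cumsum(lengths[:-1] + min_gap_bp))
        )
        starts = np.round(starts).astype(np.int64)
        domains = [
            PlantedDomain(
                int(s),
                int(s + l),
                float(rng.uniform(*depth_range)),
                cenpa_enriched=True,
            )
            for s, l in zip(starts, lengths)
        ]
        try:
            return _validate_domains(spec, domains)
        except ValueError:
            continue
    raise RuntimeError("failed to place domains")
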