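"""Domain containers and file I/O.

Three containers carry the pipeline's data:

* :class:`MethylationTrack` — per-CpG percent methylation along one contig
  (the substrate for CDR calling), read from / written to 4-column bedGraph.
* :class:`GenomicInterval` — a BED-style half-open interval with optional
  name / score / strand.
* :class:`ReadRecord` — one sequenced molecule with MM/ML-style per-position
  modification probabilities (integers 0–255) for 6mA and/or 5mC, stored in a
  documented tab-separated format (one row per read × modification type).

Haplotype is encoded in the contig name suffix (``chr5_MATERNAL`` /
``chr5_PATERNAL``) and parsed into a tag. All loaders reject malformed input
with the offending line number rather than silently repairing it, and every
writer/loader pair round-trips exactly on valid data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

MOD_TYPES = ("6mA", "5mC")

READ_TSV_HEADER = "read_id\tcontig\thaplotype\tstart\tend\tmod_type\tpositions\tprobabilities"


def parse_haplotype(contig: str) -> Optional[str]:
    """Haplotype tag from a contig name suffix, or None."""
    upper = contig.upper()
    if upper.endswith("_MATERNAL"):
        return "maternal"
    if upper.endswith("_PATERNAL"):
        return "paternal"
    return None


@dataclass
class GenomicInterval:
    """A 0-based half-open genomic interval (BED convention)."""

    contig: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval start must be < end, got [{self.start}, {self.end}) on {self.contig}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def haplotype(self) -> Optional[str]:
        return parse_haplotype(self.contig)


@dataclass
class MethylationTrack:
    """Per-CpG percent methylation for one contig/haplotype.

    Positions are strictly increasing 0-based starts; values are percent
    methylation in [0, 100].
    """

    contig: str
    positions: np.ndarray
    values: np.ndarray
    haplotype: Optional[str] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape:
            raise ValueError("positions and values must have equal length")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError(f"CpG positions on {self.contig} must be strictly increasing")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 100):
            raise ValueError("methylation values must lie in [0, 100]")
        if self.haplotype is None:
            self.haplotype = parse_haplotype(self.contig)

    def __len__(self) -> int:
        return int(self.positions.size)

    def slice(self, start: int, end: int) -> "MethylationTrack":
        """Sub-track of CpGs with start <= position < end."""
        lo, hi = np.searchsorted(self.positions, [start, end])
        return MethylationTrack(
            self.contig, self.positions[lo:hi], self.values[lo:hi], self.haplotype
        )

    def mean(self) -> float:
        return float(self.values.mean())


@dataclass
class ReadRecord:
    """One sequenced molecule with per-position modification probabilities.

    ``calls`` maps a modification type ("6mA" or "5mC") to a pair of parallel
    arrays: candidate positions (sorted, within the alignment span) and
    integer probabilities 0–255. Every candidate position carries a
    probability, as in MM/ML BAM tags; "detected" is defined downstream by a
    quality cutoff.
    """

    read_id: str
    contig: str
    start: int
    end: int
    calls: dict = field(default_factory=dict)
    haplotype: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"read {self.read_id}: start must be < end")
        if self.haplotype is None:
            self.haplotype = parse_haplotype(self.contig)
        for mod, (pos, prob) in list(self.calls.items()):
            if mod not in MOD_TYPES:
                raise ValueError(f"read {self.read_id}: unknown mod_type {mod!r}")
            pos = np.asarray(pos, dtype=np.int64)
            prob = np.asarray(prob, dtype=np.int64)
            if pos.shape != prob.shape:
                raise ValueError(f"read {self.read_id}: positions/probabilities length mismatch")
            if pos.size:
                if pos.min() < self.start or pos.max() >= self.end:
                    raise ValueError(f"read {self.read_id}: call outside alignment span")
                if np.any(np.diff(pos) <= 0):
                    raise ValueError(f"read {self.read_id}: call positions must be strictly increasing")
                if prob.min() < 0 or prob.max() > 255:
                    raise ValueError(f"read {self.read_id}: probabilities must lie in [0, 255]")
            self.calls[mod] = (pos, prob)

    def __len__(self) -> int:
        return self.end - self.start

    def calls_in(self, mod_type: str, start: int, end: int) -> tuple[np.ndarray, np.ndarray]:
        """Candidate positions and probabilities within [start, end)."""
        if mod_type not in self.calls:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        pos, prob = self.calls[mod_type]
        lo, hi = np.searchsorted(pos, [start, end])
        return pos[lo:hi], prob[lo:hi]


# ---------------------------------------------------------------------------
# bedGraph


def load_methylation_bedgraph(
    path, contig_filter: Optional[str] = None
) -> dict[str, MethylationTrack]:
    """Load a 4-column methylation bedGraph into one track per contig.

    The value column is percent methylation in [0, 100]; files whose values
    all lie in [0, 1] are auto-rescaled to percent with a warning. Mixing the
    two scales in one file is an error, as are duplicate positions.
    """
    per_contig: dict[str, list[tuple[int, float]]] = {}
    values_seen: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns, got {len(fields)}")
            contig = fields[0]
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed bedGraph line") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            if contig_filter is not None and contig != contig_filter:
                continue
            per_contig.setdefault(contig, []).append((start, value))
            values_seen.append(value)

    if values_seen:
        arr = np.asarray(values_seen)
        if arr.max() <= 1.0 and arr.min() >= 0.0:
            warnings.warn(
                f"{path}: values lie in [0, 1]; interpreting as fractions and rescaling to percent"
            )
            per_contig = {
                c: [(p, v * 100.0) for p, v in rows] for c, rows in per_contig.items()
            }
        elif arr.max() > 1.0 and np.mean((arr > 0) & (arr < 1.0)) > 0.1:
            # a percent-scale file may contain a few near-zero percents, but a
            # large share of sub-1 values alongside values > 1 is a scale mix
            raise ValueError(
                f"{path}: mixed value scales (many values in (0,1) alongside values > 1); "
                "refusing to guess"
            )
        if arr.max() > 100.0 or arr.min() < 0.0:
            raise ValueError(f"{path}: methylation values outside [0, 100]")

    tracks = {}
    for contig, rows in per_contig.items():
        rows.sort()
        positions = np.array([p for p, _ in rows], dtype=np.int64)
        if positions.size and np.any(np.diff(positions) == 0):
            raise ValueError(f"{path}: duplicate CpG position on {contig}")
        values = np.array([v for _, v in rows], dtype=float)
        tracks[contig] = MethylationTrack(contig, positions, values)
    return tracks


def write_methylation_bedgraph(tracks: Iterable[MethylationTrack], path) -> None:
    """Write tracks as 4-column bedGraph (each CpG a 1-bp interval)."""
    with open(path, "w") as fh:
        for track in tracks:
            for pos, val in zip(track.positions, track.values):
                fh.write(f"{track.contig}\t{pos}\t{pos + 1}\t{float(val)!r}\n")


# ---------------------------------------------------------------------------
# BED


def load_intervals_bed(path) -> list[GenomicInterval]:
    """Parse BED3–BED6 into half-open intervals, preserving optional columns."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 and fields[5] != "." else None
            out.append(GenomicInterval(fields[0], start, end, name, score, strand))
    return out


def write_intervals_bed(intervals: Iterable[GenomicInterval], path) -> None:
    """Write intervals as BED, emitting name/score/strand columns when present."""
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.contig, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None or iv.strand is not None:
                fields.append(f"{iv.score:g}" if iv.score is not None else ".")
            if iv.strand is not None:
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# read-record TSV


def load_read_records(path) -> list[ReadRecord]:
    """Load the read-record TSV (one row per read x modification type)."""
    by_read: dict[tuple[str, str, int, int], dict] = {}
    order: list[tuple[str, str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("read_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) != 8:
                raise ValueError(f"{path}:{lineno}: expected 8 columns, got {len(fields)}")
            read_id, contig, hap, start, end, mod, pos_s, prob_s = fields
            try:
                start, end = int(start), int(end)
                positions = (
                    np.array(pos_s.split(","), dtype=np.int64) if pos_s else np.empty(0, np.int64)
                )
                probs = (
                    np.array(prob_s.split(","), dtype=np.int64) if prob_s else np.empty(0, np.int64)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric field") from exc
            if positions.size != probs.size:
                raise ValueError(
                    f"{path}:{lineno}: read {read_id}: positions/probabilities length mismatch"
                )
            key = (read_id, contig, start, end)
            if key not in by_read:
                by_read[key] = {"haplotype": hap if hap != "." else None, "calls": {}}
                order.append(key)
            by_read[key]["calls"][mod] = (positions, probs)

    records = []
    for key in order:
        read_id, contig, start, end = key
        info = by_read[key]
        records.append(
            ReadRecord(read_id, contig, start, end, info["calls"], info["haplotype"])
        )
    return records


def write_read_records(records: Iterable[ReadRecord], path) -> None:
    """Write read records as the documented TSV (header + one row per mod)."""
    with open(path, "w") as fh:
        fh.write(READ_TSV_HEADER + "\n")
        for rec in records:
            hap = rec.haplotype if rec.haplotype is not None else "."
            for mod, (pos, prob) in rec.calls.items():
                fh.write(
                    f"{rec.read_id}\t{rec.contig}\t{hap}\t{rec.start}\t{rec.end}\t{mod}\t"
                    + ",".join(map(str, pos))
                    + "\t"
                    + ",".join(map(str, prob))
                    + "\n"
                )


# ---------------------------------------------------------------------------
# fixed-step wiggle export


def write_fixedstep_wig(
    path, contig: str, start: int, step: int, values: Sequence[float], name: str = "track"
) -> None:
    """Write a fixed-step wiggle track (1-based start per wiggle convention).

    Missing bins (NaN) are written as 'nan' so bin count is preserved.
    """
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{name}"\n')
        fh.write(f"fixedStep chrom={contig} start={start + 1} step={step} span={step}\n")
        for v in values:
            fh.write(f"{v:g}\n" if np.isfinite(v) else "nan\n")
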