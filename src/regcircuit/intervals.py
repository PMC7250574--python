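"""Genomic-interval arithmetic for ATAC-seq peak sets.

Peaks live in BED convention (0-based, half-open); gene annotation is read
from GFF3 (1-based, closed) and converted on input.  Distances between a
peak and a transcription start site (TSS) are measured from the peak
midpoint and signed by gene strand, so that upstream of the gene is
negative regardless of orientation.
"""

from __future__ import annotations

import bisect
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "TSSRecord",
    "PeakAnnotation",
    "read_bed",
    "write_bed",
    "extract_tss",
    "merge_intervals",
    "overlap_sets",
    "OverlapResult",
    "TSSIndex",
    "nearest_tss",
    "annotate_peaks",
    "write_annotation_table",
    "read_annotation_table",
    "DistanceProfile",
    "tss_distance_profile",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic span ``[start, end)`` on a chromosome."""

    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"malformed interval {self.name or '?'}: "
                f"{self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class TSSRecord:
    """One transcription start site: a 0-based point with a gene id."""

    chrom: str
    pos: int
    gene_id: str
    strand: str = "+"


@dataclass(frozen=True)
class PeakAnnotation:
    """Peak-to-nearest-gene assignment.

    ``distance`` is peak midpoint minus TSS position, with the sign
    flipped on minus-strand genes so that negative always means upstream
    of the gene.  ``gene_id`` is None (status ``no_tss``) when the peak's
    chromosome carries no TSS at all.
    """

    peak: str
    gene_id: Optional[str]
    distance: Optional[int]
    status: str = "ok"


# ---------------------------------------------------------------------------
# I/O


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/4/6 into intervals; malformed lines raise naming the line."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start_s, end_s = fields[:3]
            name = fields[3] if len(fields) > 3 else f"region_{lineno}"
            strand = fields[5] if len(fields) > 5 else "."
            try:
                iv = GenomicInterval(chrom, int(start_s), int(end_s), name, strand)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            out.append(iv)
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n"
            )


def extract_tss(
    gff_path: str | Path, feature_types: Sequence[str] = ("gene", "mRNA")
) -> list[TSSRecord]:
    """Pull TSS records out of a GFF3 file.

    For a plus-strand feature the TSS is the (1-based) start converted to
    0-based; for a minus-strand feature it is the end, likewise converted.
    Gene ids come from the ``ID=`` attribute.
    """
    records: list[TSSRecord] = []
    with open(gff_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] not in feature_types:
                continue
            chrom, start, end, strand, attrs = f[0], int(f[3]), int(f[4]), f[6], f[8]
            gene_id = None
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    gene_id = kv[3:]
                    break
            if gene_id is None:
                continue
            pos = start - 1 if strand != "-" else end - 1
            records.append(TSSRecord(chrom, pos, gene_id, strand if strand in "+-" else "+"))
    return records


# ---------------------------------------------------------------------------
# Merge and set contrasts


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or bookended (end == start) intervals per chromosome.

    Returns a sorted, non-overlapping list covering the same set of bases.
    Merged intervals are renamed ``merged_<i>`` unless they are a single
    untouched input interval, whose name is kept.
    """
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in intervals:
        by_chrom[iv.chrom].append(iv)
    merged: list[GenomicInterval] = []
    counter = 0
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        members = [ivs[0]]
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlap or bookended
                cur_end = max(cur_end, iv.end)
                members.append(iv)
            else:
                merged.append(_emit_merged(chrom, cur_start, cur_end, members, counter))
                counter += 1
                cur_start, cur_end, members = iv.start, iv.end, [iv]
        merged.append(_emit_merged(chrom, cur_start, cur_end, members, counter))
        counter += 1
    return merged


def _emit_merged(
    chrom: str, start: int, end: int, members: list[GenomicInterval], idx: int
) -> GenomicInterval:
    if len(members) == 1:
        return members[0]
    return GenomicInterval(chrom, start, end, f"merged_{idx}", ".")


@dataclass
class OverlapResult:
    """Partition of two interval sets by >=1 bp overlap with the other set."""

    unique_a: list[GenomicInterval] = field(default_factory=list)
    shared_a: list[GenomicInterval] = field(default_factory=list)
    shared_b: list[GenomicInterval] = field(default_factory=list)
    unique_b: list[GenomicInterval] = field(default_factory=list)

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (
            len(self.unique_a),
            len(self.shared_a),
            len(self.shared_b),
            len(self.unique_b),
        )


def overlap_sets(
    set_a: Sequence[GenomicInterval], set_b: Sequence[GenomicInterval]
) -> OverlapResult:
    """Classify each interval as shared (overlaps the other set) or unique.

    Shared counts are reported from each side, so ``len(shared_a)`` and
    ``len(shared_b)`` can differ when overlaps are not one-to-one.
    """
    res = OverlapResult()
    for ivs, other, uniq, shared in (
        (set_a, set_b, res.unique_a, res.shared_a),
        (set_b, set_a, res.unique_b, res.shared_b),
    ):
        starts: dict[str, list[int]] = defaultdict(list)
        ends: dict[str, list[int]] = defaultdict(list)
        for o in sorted(other, key=lambda x: (x.chrom, x.start, x.end)):
            starts[o.chrom].append(o.start)
            ends[o.chrom].append(o.end)
        # max running end so a single bisect over starts suffices
        run_end: dict[str, list[int]] = {}
        for chrom in starts:
            acc, m = [], 0
            for e in ends[chrom]:
                m = max(m, e)
                acc.append(m)
            run_end[chrom] = acc
        for iv in ivs:
            ss = starts.get(iv.chrom)
            hit = False
            if ss:
                i = bisect.bisect_left(ss, iv.end)  # others starting before iv.end
                if i > 0 and run_end[iv.chrom][i - 1] > iv.start:
                    hit = True
            (shared if hit else uniq).append(iv)
    return res


# ---------------------------------------------------------------------------
# Nearest TSS


class TSSIndex:
    """Per-chromosome sorted TSS positions for nearest-site queries."""

    def __init__(self, records: Iterable[TSSRecord]):
        tmp: dict[str, list[TSSRecord]] = defaultdict(list)
        for r in records:
            tmp[r.chrom].append(r)
        self._by_chrom: dict[str, tuple[list[int], list[TSSRecord]]] = {}
        for chrom, recs in tmp.items():
            recs = sorted(recs, key=lambda r: (r.pos, r.gene_id))
            self._by_chrom[chrom] = ([r.pos for r in recs], recs)

    def nearest(self, chrom: str, point: int) -> Optional[TSSRecord]:
        """TSS minimising |point - pos|; ties broken by lexicographic gene id."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        positions, recs = entry
        i = bisect.bisect_left(positions, point)
        candidates: list[TSSRecord] = []
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(recs):
                d = abs(positions[j] - point)
                if best is None or d < best:
                    best = d
        # collect every record at the minimal distance (duplicated positions)
        for j in range(i - 1, -1, -1):
            if abs(positions[j] - point) != best:
                break
            candidates.append(recs[j])
        for j in range(i, len(recs)):
            if abs(positions[j] - point) != best:
                break
            candidates.append(recs[j])
        return min(candidates, key=lambda r: r.gene_id)


def nearest_tss(peak: GenomicInterval, tss: TSSIndex | Iterable[TSSRecord]) -> PeakAnnotation:
    """Assign a peak to the gene whose TSS is closest to the peak midpoint."""
    index = tss if isinstance(tss, TSSIndex) else TSSIndex(tss)
    rec = index.nearest(peak.chrom, peak.midpoint)
    if rec is None:
        return PeakAnnotation(peak.name, None, None, status="no_tss")
    d = peak.midpoint - rec.pos
    if rec.strand == "-":
        d = -d
    return PeakAnnotation(peak.name, rec.gene_id, d)


def annotate_peaks(
    peaks: Iterable[GenomicInterval], tss_records: Iterable[TSSRecord]
) -> list[PeakAnnotation]:
    index = TSSIndex(tss_records)
    return [nearest_tss(p, index) for p in peaks]


def write_annotation_table(annotations: Iterable[PeakAnnotation], path: str | Path) -> None:
    df = pd.DataFrame(
        [(a.peak, a.gene_id if a.gene_id is not None else "", a.distance, a.status)
         for a in annotations],
        columns=["peak", "gene", "distance", "status"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_annotation_table(path: str | Path) -> list[PeakAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"peak": str, "gene": str})
    out = []
    for row in df.itertuples(index=False):
        gene = None if (pd.isna(row.gene) or row.gene == "") else str(row.gene)
        dist = None if pd.isna(row.distance) else int(row.distance)
        out.append(PeakAnnotation(str(row.peak), gene, dist, str(row.status)))
    return out


# ---------------------------------------------------------------------------
# Distance-to-TSS profile


@dataclass
class DistanceProfile:
    bin_edges: np.ndarray
    counts: np.ndarray
    distances: np.ndarray

    def fraction_within(self, d: int) -> float:
        """Share of annotated peaks whose |distance| <= d (over all peaks)."""
        if self.distances.size == 0:
            return float("nan")
        return float(np.mean(np.abs(self.distances) <= d))


def tss_distance_profile(
    annotations: Iterable[PeakAnnotation], bin_width: int = 100, window: int = 2000
) -> DistanceProfile:
    """Histogram of signed midpoint-to-TSS distances over [-window, +window]."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    dists = np.array(
        [a.distance for a in annotations if a.distance is not None], dtype=float
    )
    if dists.size == 0:
        raise ValueError("no annotated peaks to profile")
    edges = np.arange(-window, window + bin_width, bin_width, dtype=float)
    counts, _ = np.histogram(dists, bins=edges)
    return DistanceProfile(edges, counts, dists)
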