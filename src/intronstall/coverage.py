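"""Per-base coverage tracks from aligned reads or bedGraph, plus RPM scaling.

Reads are counted over their full aligned reference span (CIGAR-aware) after
a mapping-quality filter (default MAPQ >= 20, uniquely mapped).  Depth
normalization is reads-per-million mapped (RPM): value * 1e6 / total reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pysam

from .exceptions import EmptyTrackError, FormatError, NormalizationError
from .models import CoverageTrack

logger = logging.getLogger(__name__)

# CIGAR operations that consume the reference and should receive coverage
# (M, D, =, X); N consumes reference but is a spliced gap, no coverage.
_COVERED_OPS = {0, 2, 7, 8}
_REF_OPS = {0, 2, 3, 7, 8}


@dataclass
class ReadFilters:
    """Read selection policy for pileup construction."""

    mapq_min: int = 20
    include_duplicates: bool = True
    extend_to: int | None = None  # optional fragment extension, off by default


def read_alignments(
    alignments: str,
    filters: ReadFilters | None = None,
    source_label: str = "",
) -> CoverageTrack:
    """Pile up a coordinate-sorted, indexed BAM into raw per-base counts.

    Secondary/supplementary/unmapped records are always skipped; mates of a
    pair are counted independently.  Each retained read adds 1 to every
    reference base its alignment covers (M/D/=/X; N gaps excluded).
    """
    filters = filters or ReadFilters()
    try:
        bam = pysam.AlignmentFile(alignments, "rb")
        bam.check_index()
    except (ValueError, OSError) as exc:
        raise FormatError(f"{alignments}: missing or unreadable index ({exc})") from exc

    values = {
        name: np.zeros(length, dtype=np.float64)
        for name, length in zip(bam.references, bam.lengths)
    }
    n_retained = 0
    for chrom in bam.references:
        arr = values[chrom]
        L = len(arr)
        for read in bam.fetch(chrom):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < filters.mapq_min:
                continue
            if not filters.include_duplicates and read.is_duplicate:
                continue
            n_retained += 1
            pos = read.reference_start
            if filters.extend_to is not None:
                start = pos if not read.is_reverse else max(0, read.reference_end - filters.extend_to)
                end = min(L, start + filters.extend_to)
                arr[start:end] += 1
                continue
            for op, length in read.cigartuples or ():
                if op in _COVERED_OPS:
                    arr[pos : min(L, pos + length)] += 1
                if op in _REF_OPS:
                    pos += length
    bam.close()
    if n_retained == 0:
        raise EmptyTrackError(f"{alignments}: no reads pass filters (mapq_min={filters.mapq_min})")
    return CoverageTrack(values=values, value_kind="raw_counts", total_mapped_reads=n_retained, source_label=source_label)


def read_bedgraph(
    track: str,
    total_mapped_reads: int | None = None,
    chrom_lengths: dict[str, int] | None = None,
    source_label: str = "",
) -> CoverageTrack:
    """Load a bedGraph into dense per-base arrays.

    The library size is taken from a ``#total_mapped=N`` header line unless
    passed explicitly; chromosome lengths come from a ``#chrom_lengths=``
    header (``name:len;name:len``), an explicit argument, or default to the
    maximum interval end per chromosome.  Intervals must be sorted and
    non-overlapping within each chromosome.
    """
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    header_lengths: dict[str, int] = {}
    with open(track) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser")):
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("total_mapped="):
                    total_mapped_reads = total_mapped_reads or int(body.split("=", 1)[1])
                elif body.startswith("chrom_lengths="):
                    for item in body.split("=", 1)[1].split(";"):
                        if item:
                            name, n = item.split(":")
                            header_lengths[name] = int(n)
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{track}: malformed bedGraph line {line!r}")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if end <= start:
                raise FormatError(f"{track}: empty interval {line!r}")
            intervals.setdefault(chrom, []).append((start, end, value))
    if not intervals:
        raise EmptyTrackError(f"{track}: no intervals")
    if total_mapped_reads is None:
        raise FormatError(f"{track}: no '#total_mapped=' header and no total_mapped_reads given")

    lengths = dict(header_lengths)
    if chrom_lengths:
        lengths.update(chrom_lengths)
    values: dict[str, np.ndarray] = {}
    for chrom, ivs in intervals.items():
        prev_end = -1
        for (s, e, _) in ivs:
            if s < prev_end:
                raise FormatError(f"{track}: overlapping/unsorted intervals on {chrom}")
            prev_end = e
        n = lengths.get(chrom, max(e for _, e, _ in ivs))
        arr = np.zeros(n, dtype=np.float64)
        for (s, e, v) in ivs:
            arr[s:e] = v
        values[chrom] = arr
    return CoverageTrack(values=values, value_kind="raw_counts", total_mapped_reads=int(total_mapped_reads), source_label=source_label)


def write_bedgraph(track: CoverageTrack, path: str) -> None:
    """Write a track as run-length-encoded bedGraph with metadata headers.

    Zero-valued runs are written too, so read_bedgraph(write_bedgraph(t))
    round-trips exactly (up to float formatting).
    """
    with open(path, "w") as fh:
        fh.write(f"#total_mapped={track.total_mapped_reads}\n")
        lens = ";".join(f"{c}:{len(v)}" for c, v in track.values.items())
        fh.write(f"#chrom_lengths={lens}\n")
        for chrom, arr in track.values.items():
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                v = arr[s]
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")


def normalize(track: CoverageTrack) -> CoverageTrack:
    """Scale raw counts to reads-per-million mapped (RPM)."""
    if track.total_mapped_reads <= 0:
        raise NormalizationError("total_mapped_reads must be positive")
    scale = 1e6 / track.total_mapped_reads
    return CoverageTrack(
        values={c: v * scale for c, v in track.values.items()},
        value_kind="rpm",
        total_mapped_reads=track.total_mapped_reads,
        source_label=track.source_label,
    )
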