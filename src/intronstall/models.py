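"""Core in-memory containers: gene anatomy, coverage tracks, profiles.

Coordinate conventions
----------------------
All coordinates are 0-based internally.  Interval-like fields (exons, enriched
regions) are half-open ``[start, end)`` in genomic orientation.  Point-like
fields (``tss``, ``three_prime_end``, ``five_ss``, ``bp``, ``three_ss``) are
the 0-based position of a single base.  GFF3/GTF and BP-table I/O convert
from/to the 1-based closed convention at the boundary.

Transcript orientation: on the ``-`` strand "downstream" means decreasing
genomic coordinate; :func:`tx_shift` maps (anchor, offset) pairs accordingly,
so profile code never branches on strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

# Feature-class codes used in FeaturePartition.class_map arrays.
UNASSIGNED = 0
EXON1 = 1
INTRON = 2
EXON2 = 3
INTRONLESS = 4
CONFLICT = -1  # overlapping genes of conflicting class; dropped from totals

CLASS_NAMES = {EXON1: "exon1", INTRON: "intron", EXON2: "exon2", INTRONLESS: "intronless"}
CLASS_CODES = {v: k for k, v in CLASS_NAMES.items()}

ANCHORS = ("TSS", "FIVE_SS", "BP", "THREE_SS", "THREE_END")


def tx_shift(pos: int, offset: int, strand: str) -> int:
    """Genomic position `offset` bases downstream (transcript sense) of `pos`."""
    return pos + offset if strand == "+" else pos - offset


@dataclass
class IntronModel:
    """One intron, anchored by its splice sites and (optionally) branchpoint.

    ``five_ss`` is the first intronic base and ``three_ss`` the last, both in
    transcript orientation, so ``five_ss > three_ss`` genomically on ``-``
    strand genes.  ``bp`` is the branch adenosine or ``None`` when unknown.
    """

    five_ss: int
    three_ss: int
    bp: int | None = None
    bp_source: str = "none"  # {table, motif, none}

    def genomic_interval(self) -> tuple[int, int]:
        """Half-open genomic [start, end) of the intron."""
        lo, hi = sorted((self.five_ss, self.three_ss))
        return lo, hi + 1

    @property
    def length(self) -> int:
        return abs(self.three_ss - self.five_ss) + 1

    def contains_strictly(self, pos: int) -> bool:
        """True if pos lies inside the intron, excluding both splice sites."""
        lo, hi = sorted((self.five_ss, self.three_ss))
        return lo < pos < hi


@dataclass
class GeneModel:
    """Splicing-aware anatomy of one transcript.

    ``exons`` are genomic half-open intervals ordered 5'->3' in transcript
    orientation (descending genomic coordinate on the ``-`` strand); introns
    exactly fill the gaps between consecutive exons.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    three_prime_end: int
    exons: list[tuple[int, int]]
    introns: list[IntronModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.strand == "+" and not self.tss < self.three_prime_end:
            raise ValueError(f"{self.gene_id}: tss must precede 3' end on + strand")
        if self.strand == "-" and not self.tss > self.three_prime_end:
            raise ValueError(f"{self.gene_id}: tss must follow 3' end (genomic) on - strand")

    @classmethod
    def from_exons(
        cls, gene_id: str, chrom: str, strand: str, exons: Iterable[tuple[int, int]]
    ) -> "GeneModel":
        """Build a model from genomic exon intervals; introns derived from gaps."""
        ex = sorted((int(s), int(e)) for s, e in exons)
        for (s, e) in ex:
            if e <= s:
                raise ValueError(f"{gene_id}: empty exon [{s},{e})")
        for (_, e0), (s1, _) in zip(ex, ex[1:]):
            if s1 < e0:
                raise ValueError(f"{gene_id}: overlapping exons")
            if s1 == e0:
                raise ValueError(f"{gene_id}: zero-length intron between abutting exons")
        introns_genomic = [(e0, s1) for (_, e0), (s1, _) in zip(ex, ex[1:])]
        if strand == "-":
            ex = ex[::-1]
            introns_genomic = introns_genomic[::-1]
        introns = []
        for (gs, ge) in introns_genomic:
            if strand == "+":
                introns.append(IntronModel(five_ss=gs, three_ss=ge - 1))
            else:
                introns.append(IntronModel(five_ss=ge - 1, three_ss=gs))
        gstart = min(s for s, _ in ex)
        gend = max(e for _, e in ex)
        tss = gstart if strand == "+" else gend - 1
        tpe = gend - 1 if strand == "+" else gstart
        return cls(gene_id, chrom, strand, tss, tpe, ex, introns)

    @property
    def gene_class(self) -> str:
        return "intron_containing" if self.introns else "intronless"

    @property
    def span(self) -> tuple[int, int]:
        """Half-open genomic [start, end) of the whole gene body."""
        lo = min(min(s for s, _ in self.exons), min(i.genomic_interval()[0] for i in self.introns) if self.introns else np.inf)
        hi = max(max(e for _, e in self.exons), max(i.genomic_interval()[1] for i in self.introns) if self.introns else -np.inf)
        return int(lo), int(hi)

    @property
    def first_intron(self) -> IntronModel:
        if not self.introns:
            raise ValueError(f"{self.gene_id} is intronless")
        return self.introns[0]

    def anchor_position(self, anchor: str) -> int | None:
        """Genomic coordinate of a named anchor, or None if unresolvable."""
        if anchor == "TSS":
            return self.tss
        if anchor == "THREE_END":
            return self.three_prime_end
        if not self.introns:
            return None
        fi = self.first_intron
        if anchor == "FIVE_SS":
            return fi.five_ss
        if anchor == "THREE_SS":
            return fi.three_ss
        if anchor == "BP":
            return fi.bp  # None when unknown
        raise ValueError(f"unknown anchor {anchor!r}")

    def feature_intervals(self) -> list[tuple[int, int, int]]:
        """Per-feature (start, end, class_code) genomic intervals.

        For an intron-containing gene: the exon 5' of the first intron is
        exon1; every intron is intron class; all exonic sequence 3' of the
        first intron is exon2.  Intronless genes are one intronless interval.
        """
        if not self.introns:
            s, e = self.span
            return [(s, e, INTRONLESS)]
        out: list[tuple[int, int, int]] = [(self.exons[0][0], self.exons[0][1], EXON1)]
        for intr in self.introns:
            gs, ge = intr.genomic_interval()
            out.append((gs, ge, INTRON))
        for ex in self.exons[1:]:
            out.append((ex[0], ex[1], EXON2))
        return out


@dataclass
class FeaturePartition:
    """Per-base feature-class assignment and class totals over the genome."""

    class_map: dict[str, np.ndarray]  # int8 arrays, codes above
    bases: dict[str, int]
    fractions: dict[str, float]
    dropped_bases: int = 0

    @property
    def total_assigned(self) -> int:
        return sum(self.bases.values())


@dataclass
class CoverageTrack:
    """Per-base coverage over each chromosome for one condition."""

    values: dict[str, np.ndarray]
    value_kind: str  # {raw_counts, rpm}
    total_mapped_reads: int
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.value_kind not in ("raw_counts", "rpm"):
            raise ValueError(f"bad value_kind {self.value_kind!r}")

    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.values.items()}


@dataclass
class RatioTrack:
    """Per-base condition-vs-condition fold enrichment."""

    values: dict[str, np.ndarray]
    numerator_label: str
    denominator_label: str
    pseudocount: float

    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.values.items()}


@dataclass
class GeneCall:
    """Per-gene enriched-region call."""

    gene_id: str
    enriched_regions: list[tuple[int, int]]
    enriched: bool


@dataclass
class EnrichmentReport:
    threshold: float
    strict: bool
    min_run: int
    class_fractions: dict[str, float | None]
    gene_calls: list[GeneCall]

    @property
    def n_enriched_genes(self) -> int:
        return sum(c.enriched for c in self.gene_calls)


@dataclass
class MetaProfile:
    """Gene-averaged per-offset signal around one anchor (anchor at offset 0)."""

    anchor: str
    offsets: np.ndarray
    mean_value: np.ndarray
    n_genes: np.ndarray
    value_kind: str  # {rpm, ratio}

    def __post_init__(self) -> None:
        if self.anchor not in ANCHORS:
            raise ValueError(f"unknown anchor {self.anchor!r}")


@dataclass
class ScaledProfile:
    """Length-normalized binned profile over (upstream, intron, exon2) segments."""

    segment_labels: tuple[str, ...]
    bins_per_segment: tuple[int, ...]
    mean_value: np.ndarray  # concatenated across segments
    n_genes: int

    def segment_values(self) -> dict[str, np.ndarray]:
        out, i = {}, 0
        for label, nb in zip(self.segment_labels, self.bins_per_segment):
            out[label] = self.mean_value[i : i + nb]
            i += nb
        return out


@dataclass
class TranscriptQuant:
    """Linear-scale abundances for one gene in one condition/timepoint."""

    gene_id: str
    condition: str
    pre_mrna: float = 0.0
    mrna: float = 0.0
    exon2_total: float = 0.0
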