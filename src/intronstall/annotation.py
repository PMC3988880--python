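"""Genome annotation: gene models, branchpoint localization, feature partition.

The analysis views an intron-containing gene as exon1 | intron | exon2 (the
exon upstream of the first intron, the intron(s), and everything exonic
downstream of the first intron); all other genes are "intronless".  This
four-way vocabulary partitions every transcribed base of the genome and is
the denominator for all enriched-base fractions downstream.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import gffutils
import numpy as np
import pandas as pd

from .exceptions import AnnotationError, EmptyPartitionError, FormatError
from .models import (
    CLASS_NAMES,
    CONFLICT,
    EXON1,
    EXON2,
    INTRON,
    INTRONLESS,
    UNASSIGNED,
    FeaturePartition,
    GeneModel,
    IntronModel,
)

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AnnotationConfig:
    """Filters applied while loading an annotation.

    min_gene_length: genes with a shorter genomic span are excluded.
    transcript_policy: 'longest' keeps the transcript with the largest
        genomic span per gene (one transcript per gene).
    """

    min_gene_length: int = 200
    transcript_policy: str = "longest"


@dataclass
class BPParams:
    """Branchpoint motif-scan parameters (S. cerevisiae consensus TACTAAC).

    The branch adenosine is position 6 of the motif (index ``branch_index``)
    and is never allowed to mismatch.  ``min_dist_3ss``/``max_dist_3ss`` bound
    the distance (in nt) from the branch A to the last intronic base.
    """

    motif: str = "TACTAAC"
    branch_index: int = 5  # 0-based within motif
    max_mismatch: int = 1
    min_dist_3ss: int = 5
    max_dist_3ss: int = 200


def load_annotation(
    annotation_file: str,
    config: AnnotationConfig | None = None,
) -> list[GeneModel]:
    """Parse a GFF3/GTF file into one GeneModel per gene.

    One transcript per gene is selected (longest genomic span by default);
    introns are derived from the gaps between consecutive exons.  Transcripts
    with overlapping exons and genes failing the length filter are skipped
    with a logged reason.
    """
    config = config or AnnotationConfig()
    try:
        db = gffutils.create_db(
            annotation_file,
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise AnnotationError(f"cannot parse {annotation_file}: {exc}") from exc

    # transcript id -> (gene id, transcript feature)
    transcripts: dict[str, tuple[str, object]] = {}
    for ftype in ("mRNA", "transcript"):
        for t in db.features_of_type(ftype):
            gene_id = (
                t.attributes.get("Parent", [None])[0]
                or t.attributes.get("gene_id", [t.id])[0]
            )
            transcripts[t.id] = (gene_id, t)
    if not transcripts:
        raise AnnotationError(f"{annotation_file}: no mRNA/transcript features found")

    # pick one transcript per gene
    by_gene: dict[str, object] = {}
    for tid, (gene_id, t) in transcripts.items():
        cur = by_gene.get(gene_id)
        if cur is None or (t.end - t.start) > (cur.end - cur.start):
            by_gene[gene_id] = t

    genes: list[GeneModel] = []
    n_skipped = 0
    for gene_id, t in sorted(by_gene.items()):
        exons = [(f.start - 1, f.end) for f in db.children(t, featuretype="exon")]
        if not exons:
            logger.warning("gene %s: transcript %s has no exons; skipped", gene_id, t.id)
            n_skipped += 1
            continue
        try:
            gm = GeneModel.from_exons(gene_id, t.seqid, t.strand, exons)
        except ValueError as exc:
            logger.warning("gene %s skipped: %s", gene_id, exc)
            n_skipped += 1
            continue
        s, e = gm.span
        if e - s < config.min_gene_length:
            logger.info("gene %s skipped: span %d < min_gene_length %d", gene_id, e - s, config.min_gene_length)
            n_skipped += 1
            continue
        genes.append(gm)
    if n_skipped:
        logger.info("load_annotation: %d gene(s) skipped, %d kept", n_skipped, len(genes))
    return genes


def find_branchpoint(intron_sequence: str, params: BPParams | None = None) -> int | None:
    """Locate the branch adenosine in an intron sequence (5'->3').

    Scans for the best match to the consensus motif allowing up to
    ``max_mismatch`` mismatches, with the branch A itself always required to
    match.  Among equal-mismatch candidates the one closest to the 3'SS wins.
    Returns the 0-based offset of the branch A within the intron, or None if
    no match passes the distance bounds.
    """
    params = params or BPParams()
    seq = intron_sequence.upper()
    if not set(seq) <= set("ACGTN"):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"non-nucleotide characters in intron sequence: {bad}")
    motif = params.motif.upper()
    k = len(motif)
    L = len(seq)
    best: tuple[int, int, int] | None = None  # (mismatches, dist_to_3ss, offset)
    for i in range(L - k + 1):
        window = seq[i : i + k]
        if window[params.branch_index] != motif[params.branch_index]:
            continue
        mm = sum(a != b for a, b in zip(window, motif))
        if mm > params.max_mismatch:
            continue
        a_off = i + params.branch_index
        dist = (L - 1) - a_off
        if not params.min_dist_3ss <= dist <= params.max_dist_3ss:
            continue
        cand = (mm, dist, a_off)
        if best is None or cand[:2] < best[:2]:
            best = cand
    return None if best is None else best[2]


def _intron_sequence(gene: GeneModel, intron: IntronModel, genome) -> str:
    gs, ge = intron.genomic_interval()
    seq = str(genome[gene.chrom][gs:ge])
    return _revcomp(seq) if gene.strand == "-" else seq


def attach_branchpoints(
    genes: list[GeneModel],
    bp_table: str | pd.DataFrame | None = None,
    genome: str | None = None,
    params: BPParams | None = None,
) -> list[GeneModel]:
    """Assign branchpoint coordinates to every intron, in place.

    Priority: curated table (bp_source='table'), then motif scan against the
    genome FASTA (bp_source='motif'), else left unknown (bp_source='none').
    A table row whose coordinate is not strictly inside an intron of the
    named gene is rejected with a warning.  Returns the same gene list.
    """
    params = params or BPParams()
    table: dict[str, int] = {}
    if bp_table is not None:
        df = bp_table if isinstance(bp_table, pd.DataFrame) else pd.read_csv(bp_table, sep="\t")
        required = {"gene_id", "chrom", "bp_position"}
        if not required <= set(df.columns):
            raise FormatError(f"BP table needs columns {sorted(required)}")
        for _, row in df.iterrows():
            table[str(row["gene_id"])] = int(row["bp_position"]) - 1  # 1-based -> 0-based

    fasta = None
    if genome is not None:
        import pyfaidx

        fasta = pyfaidx.Fasta(genome)

    counts = {"table": 0, "motif": 0, "none": 0}
    for gene in genes:
        for intron in gene.introns:
            pos = table.get(gene.gene_id)
            if pos is not None:
                if intron.contains_strictly(pos):
                    intron.bp, intron.bp_source = pos, "table"
                    counts["table"] += 1
                    continue
                logger.warning(
                    "BP table row for %s rejected: position %d not strictly inside intron",
                    gene.gene_id,
                    pos + 1,
                )
            if fasta is not None:
                seq = _intron_sequence(gene, intron, fasta)
                off = find_branchpoint(seq, params)
                if off is not None:
                    intron.bp = (
                        intron.five_ss + off if gene.strand == "+" else intron.five_ss - off
                    )
                    intron.bp_source = "motif"
                    counts["motif"] += 1
                    continue
            intron.bp, intron.bp_source = None, "none"
            counts["none"] += 1
    logger.info("attach_branchpoints: %s", counts)
    return genes


def feature_partition(
    genes: list[GeneModel],
    chrom_lengths: dict[str, int] | None = None,
    policy: str = "drop_conflicts",
) -> FeaturePartition:
    """Partition gene-body bases into {exon1, intron, exon2, intronless}.

    Bases covered by overlapping genes of conflicting class are handled by
    ``policy``: 'drop_conflicts' removes them from all totals;
    'priority_intron_containing' lets intron-containing-gene classes override
    intronless, dropping only intron-containing vs intron-containing clashes.
    Fractions are computed over assigned bases and sum to 1.
    """
    if policy not in ("drop_conflicts", "priority_intron_containing"):
        raise ValueError(f"unknown overlap policy {policy!r}")
    if not genes:
        raise EmptyPartitionError("no genes supplied")
    if chrom_lengths is None:
        chrom_lengths = {}
        for g in genes:
            _, e = g.span
            chrom_lengths[g.chrom] = max(chrom_lengths.get(g.chrom, 0), e)

    class_map = {c: np.zeros(n, dtype=np.int8) for c, n in chrom_lengths.items()}
    ic_codes = (EXON1, INTRON, EXON2)
    for gene in genes:
        arr = class_map[gene.chrom]
        for (s, e, code) in gene.feature_intervals():
            seg = arr[s:e]
            fresh = seg == UNASSIGNED
            same = seg == code
            clash = ~(fresh | same) & (seg != CONFLICT)
            if policy == "priority_intron_containing":
                if code in ic_codes:
                    overridable = clash & (seg == INTRONLESS)
                    seg[overridable] = code
                    clash &= ~overridable
                else:  # intronless never overrides intron-containing classes
                    keep = clash & np.isin(seg, ic_codes)
                    clash &= ~keep
            seg[clash] = CONFLICT
            seg[fresh] = code

    bases = {name: 0 for name in CLASS_NAMES.values()}
    dropped = 0
    for arr in class_map.values():
        for code, name in CLASS_NAMES.items():
            bases[name] += int((arr == code).sum())
        dropped += int((arr == CONFLICT).sum())
    total = sum(bases.values())
    if total == 0:
        raise EmptyPartitionError("partition assigned zero bases")
    fractions = {name: n / total for name, n in bases.items()}
    return FeaturePartition(class_map=class_map, bases=bases, fractions=fractions, dropped_bases=dropped)


def partition_to_bed(genes: list[GeneModel]) -> str:
    """BED6 text with one record per feature instance (name = class)."""
    lines = []
    for g in genes:
        for (s, e, code) in g.feature_intervals():
            lines.append(f"{g.chrom}\t{s}\t{e}\t{CLASS_NAMES[code]}\t0\t{g.strand}")
    return "\n".join(lines) + "\n"


def partition_summary_json(partition: FeaturePartition) -> str:
    summary = {
        name: {"bases": partition.bases[name], "fraction": partition.fractions[name]}
        for name in partition.bases
    }
    summary["dropped_bases"] = partition.dropped_bases
    return json.dumps(summary, indent=2)


def write_partition(genes: list[GeneModel], partition: FeaturePartition, out_prefix: str) -> None:
    """Write <prefix>.bed and <prefix>.json for a computed partition."""
    os.makedirs(os.path.dirname(out_prefix) or ".", exist_ok=True)
    with open(out_prefix + ".bed", "w") as fh:
        fh.write(partition_to_bed(genes))
    with open(out_prefix + ".json", "w") as fh:
        fh.write(partition_summary_json(partition))
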