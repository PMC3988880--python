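"""Fold-enrichment ratio tracks, enriched-base fractions, per-gene calls.

The central comparison is mutant-vs-WT RPM coverage per base:
``(num + pseudocount) / (den + pseudocount)``.  A base is "enriched" when
that ratio exceeds a fold threshold (default strictly > 2).  Class-level
enrichment is the fraction of bases of each feature class that are enriched;
gene-level calls require a run of at least ``min_run`` consecutive enriched
bases inside the gene body.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .exceptions import ShapeMismatchError
from .models import (
    CLASS_CODES,
    CoverageTrack,
    EnrichmentReport,
    GeneCall,
    GeneModel,
    FeaturePartition,
    RatioTrack,
)


def ratio_track(
    numerator: CoverageTrack,
    denominator: CoverageTrack,
    pseudocount: float = 1.0,
) -> RatioTrack:
    """Per-base fold enrichment of one RPM track over another.

    Both tracks must be RPM-normalized over identical chromosome sets and
    lengths.  The pseudocount (RPM units) is added to both numerator and
    denominator, stabilizing low-coverage bases.
    """
    if numerator.value_kind != "rpm" or denominator.value_kind != "rpm":
        raise ValueError("ratio_track requires rpm-normalized tracks")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if numerator.chrom_lengths() != denominator.chrom_lengths():
        raise ShapeMismatchError(
            f"chromosome mismatch: {numerator.chrom_lengths()} vs {denominator.chrom_lengths()}"
        )
    values = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for chrom, num in numerator.values.items():
            den = denominator.values[chrom]
            values[chrom] = (num + pseudocount) / (den + pseudocount)
    return RatioTrack(
        values=values,
        numerator_label=numerator.source_label,
        denominator_label=denominator.source_label,
        pseudocount=pseudocount,
    )


def enriched_mask(
    ratio: RatioTrack, threshold: float = 2.0, strict: bool = True
) -> dict[str, np.ndarray]:
    """Boolean per-base mask of enriched positions (ratio > threshold)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    op = np.greater if strict else np.greater_equal
    return {chrom: op(vals, threshold) for chrom, vals in ratio.values.items()}


def feature_enrichment_fraction(
    mask: dict[str, np.ndarray], partition: FeaturePartition
) -> dict[str, float | None]:
    """Fraction of bases of each feature class that are enriched.

    A class with zero bases in the partition reports None (undefined), never 0.
    """
    enriched = {name: 0 for name in CLASS_CODES}
    for chrom, cmap in partition.class_map.items():
        if chrom not in mask:
            raise ShapeMismatchError(f"mask lacks chromosome {chrom}")
        m = mask[chrom]
        if len(m) != len(cmap):
            raise ShapeMismatchError(f"mask/partition length mismatch on {chrom}")
        for name, code in CLASS_CODES.items():
            enriched[name] += int(np.count_nonzero(m & (cmap == code)))
    return {
        name: (enriched[name] / partition.bases[name]) if partition.bases[name] > 0 else None
        for name in CLASS_CODES
    }


def _true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end) runs of True in a boolean array."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def call_enriched_genes(
    mask: dict[str, np.ndarray],
    genes: list[GeneModel],
    min_run: int = 10,
) -> list[GeneCall]:
    """Per-gene enriched-region calls.

    Within each gene body, maximal runs of enriched bases of length
    >= min_run become enriched regions (genomic half-open coordinates); a
    gene is called enriched iff it has at least one such region.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    calls = []
    for gene in genes:
        s, e = gene.span
        m = mask[gene.chrom][s:e]
        regions = [
            (s + rs, s + re) for rs, re in _true_runs(m) if re - rs >= min_run
        ]
        calls.append(GeneCall(gene_id=gene.gene_id, enriched_regions=regions, enriched=bool(regions)))
    return calls


def enrichment_report(
    ratio: RatioTrack,
    partition: FeaturePartition,
    genes: list[GeneModel],
    threshold: float = 2.0,
    strict: bool = True,
    min_run: int = 10,
) -> EnrichmentReport:
    """One-call convenience wrapper: mask -> class fractions -> gene calls."""
    mask = enriched_mask(ratio, threshold=threshold, strict=strict)
    fractions = feature_enrichment_fraction(mask, partition)
    calls = call_enriched_genes(mask, genes, min_run=min_run)
    return EnrichmentReport(
        threshold=threshold,
        strict=strict,
        min_run=min_run,
        class_fractions=fractions,
        gene_calls=calls,
    )


def report_to_json(report: EnrichmentReport) -> str:
    return json.dumps(
        {
            "threshold": report.threshold,
            "strict": report.strict,
            "min_run": report.min_run,
            "class_fractions": report.class_fractions,
            "n_enriched_genes": report.n_enriched_genes,
            "genes": [
                {
                    "gene_id": c.gene_id,
                    "enriched": c.enriched,
                    "regions": [list(r) for r in c.enriched_regions],
                }
                for c in report.gene_calls
            ],
        },
        indent=2,
    )


def gene_calls_table(report: EnrichmentReport) -> pd.DataFrame:
    """Per-gene call table (mirrors a supplementary gene list)."""
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in report.gene_calls],
            "enriched": [c.enriched for c in report.gene_calls],
            "n_regions": [len(c.enriched_regions) for c in report.gene_calls],
            "enriched_bases": [
                sum(e - s for s, e in c.enriched_regions) for c in report.gene_calls
            ],
        }
    )


def regions_to_bed(report: EnrichmentReport, genes: list[GeneModel]) -> str:
    """Enriched regions as BED (name = gene id)."""
    chrom_of = {g.gene_id: g.chrom for g in genes}
    lines = []
    for call in report.gene_calls:
        for s, e in call.enriched_regions:
            lines.append(f"{chrom_of[call.gene_id]}\t{s}\t{e}\t{call.gene_id}")
    return "\n".join(lines) + ("\n" if lines else "")
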