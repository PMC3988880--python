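"""Shared fixtures: hand-built gene models and the study-scale simulation."""

from __future__ import annotations

import numpy as np
import pytest

import intronstall as it


@pytest.fixture
def hand_genes():
    """Two genes on a 1.5 kb chromosome: one 2-exon (+), one intronless.

    geneA: exon1 [0,100), intron [100,300), exon2 [300,600), + strand.
    geneB: intronless [700,1200), + strand.
    """
    a = it.GeneModel.from_exons("geneA", "chrT", "+", [(0, 100), (300, 600)])
    b = it.GeneModel.from_exons("geneB", "chrT", "+", [(700, 1200)])
    return [a, b]


@pytest.fixture
def chrom_lengths():
    return {"chrT": 1500}


def make_track(values: dict[str, np.ndarray], kind="rpm", total=1_000_000, label=""):
    return it.CoverageTrack(
        values={c: np.asarray(v, dtype=float) for c, v in values.items()},
        value_kind=kind,
        total_mapped_reads=total,
        source_label=label,
    )


@pytest.fixture(scope="session")
def study():
    """Default study conditions: 200 genes, 5% intron-containing, depth 20,
    stall fold 4 over 5'SS..BP in the mutant, 30% post-3'SS drop, seed 7."""
    cfg = it.SimulationConfig()
    gff3, fasta, genes = it.simulate_annotation(cfg)
    chrom_length = sum(len(l) for l in fasta.splitlines()[1:])
    truth = it.planted_truth(genes, cfg)
    wt = it.normalize(it.simulate_coverage(genes, truth, cfg, "wt", chrom_length))
    mt = it.normalize(it.simulate_coverage(genes, truth, cfg, "mutant", chrom_length))
    ratio = it.ratio_track(mt, wt, pseudocount=1.0)
    partition = it.feature_partition(genes, {cfg.chrom_name: chrom_length})
    return {
        "config": cfg,
        "genes": genes,
        "truth": truth,
        "chrom_length": chrom_length,
        "wt": wt,
        "mt": mt,
        "ratio": ratio,
        "partition": partition,
    }


@pytest.fixture(scope="session")
def null_study():
    """Matched no-stall control: identical expected coverage in both conditions."""
    cfg = it.null_config()
    gff3, fasta, genes = it.simulate_annotation(cfg)
    chrom_length = sum(len(l) for l in fasta.splitlines()[1:])
    truth = it.planted_truth(genes, cfg)
    wt = it.normalize(it.simulate_coverage(genes, truth, cfg, "wt", chrom_length))
    mt = it.normalize(it.simulate_coverage(genes, truth, cfg, "mutant", chrom_length))
    ratio = it.ratio_track(mt, wt, pseudocount=1.0)
    partition = it.feature_partition(genes, {cfg.chrom_name: chrom_length})
    return {
        "config": cfg,
        "genes": genes,
        "truth": truth,
        "chrom_length": chrom_length,
        "wt": wt,
        "mt": mt,
        "ratio": ratio,
        "partition": partition,
    }


def mirror_genes(genes, chrom_lengths):
    """Reflect all coordinates (p -> L-1-p) and flip strands."""
    out = []
    for g in genes:
        L = chrom_lengths[g.chrom]
        exons = [(L - e, L - s) for s, e in g.exons]
        strand = "-" if g.strand == "+" else "+"
        m = it.GeneModel.from_exons(g.gene_id, g.chrom, strand, exons)
        for mi, gi in zip(m.introns, g.introns):
            if gi.bp is not None:
                mi.bp, mi.bp_source = L - 1 - gi.bp, gi.bp_source
        out.append(m)
    return out


def mirror_track(track):
    return it.CoverageTrack(
        values={c: v[::-1].copy() for c, v in track.values.items()},
        value_kind=track.value_kind,
        total_mapped_reads=track.total_mapped_reads,
        source_label=track.source_label,
    )
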