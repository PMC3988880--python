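"""Synthetic yeast-like ChIP-seq data with planted intronic Pol II stalling.

The generator emulates the study design the pipeline targets: a genome in
which only a small minority (~5%) of genes carry a (single, 5'-proximal)
intron; per-base Pol II occupancy with a 5' peak in both conditions; and, in
the "mutant" condition only, a configurable fold accumulation over the
region from the 5' splice site to the branchpoint plus a post-3'SS coverage
drop.  Counts are Poisson per base.  Because the stall location and fold are
known (the truth table), every downstream stage — branchpoint recovery,
enrichment fractions, gene calls, metaprofiles, significance — can be scored
against planted truth.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pysam

from .exceptions import CapacityError
from .models import CoverageTrack, GeneModel

_BASES = np.array(list("ACGT"))
_BP_MOTIF = "TACTAAC"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic genome and coverage.

    Defaults encode the yeast-like regime the analysis assumes: 5% of genes
    intron containing, introns near the 5' end, mean occupancy ("depth") 20
    on gene bodies over a background of 1 (5% background noise), a 3-fold 5'
    occupancy peak in both conditions, and in the mutant a 4-fold stall over
    the 5'SS-to-BP segment with a 30% post-3'SS coverage drop.
    """

    n_genes: int = 200
    intron_containing_fraction: float = 0.05
    exon1_length: tuple[int, int] = (100, 300)
    intron_length: tuple[int, int] = (100, 400)
    exon2_length: tuple[int, int] = (300, 800)
    intronless_length: tuple[int, int] = (500, 1500)
    intergenic_spacing: tuple[int, int] = (100, 300)
    bp_distance_to_3ss: tuple[int, int] = (20, 60)
    baseline_occupancy: float = 20.0
    background: float = 1.0
    five_prime_peak_fold: float = 3.0
    five_prime_peak_span: int = 100
    stall_fold: float = 4.0
    stall_region: str = "five_ss_to_bp"  # or "intron"
    post_3ss_drop: float = 0.3
    read_length: int = 50
    chrom_name: str = "chrS"
    chrom_length: int | None = None  # None: sized to fit the genes
    seed: int = 7

    def validate(self) -> None:
        if self.n_genes < 1:
            raise CapacityError(f"n_genes must be >= 1, got {self.n_genes}")
        if not 0 <= self.intron_containing_fraction <= 1:
            raise ValueError("intron_containing_fraction must be in [0,1]")
        if min(self.stall_fold, self.five_prime_peak_fold) < 0:
            raise ValueError("folds must be >= 0")
        if not 0 <= self.post_3ss_drop <= 1:
            raise ValueError("post_3ss_drop must be in [0,1]")
        if self.stall_region not in ("five_ss_to_bp", "intron"):
            raise ValueError(f"unknown stall_region {self.stall_region!r}")


@dataclass
class TruthRecord:
    gene_id: str
    gene_class: str
    stalled: bool
    stall_start: int  # genomic half-open; -1/-1 when no stall region
    stall_end: int
    applied_fold: float


@dataclass
class TruthTable:
    records: list[TruthRecord] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "TruthTable":
        df = pd.read_csv(path, sep="\t")
        return cls([TruthRecord(**{k: row[k] for k in TruthRecord.__dataclass_fields__}) for _, row in df.iterrows()])

    def stalled_ids(self) -> set[str]:
        return {r.gene_id for r in self.records if r.stalled}


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _make_intron_seq(rng: np.random.Generator, length: int, bp_dist: int) -> tuple[str, int]:
    """Intron sequence (5'->3') with exactly one exact branch motif.

    Returns (sequence, branch A offset).  The intron starts GTATGT, ends AG,
    and carries a single planted TACTAAC whose branch A sits ``bp_dist`` nt
    upstream of the last intronic base; random sequence elsewhere is
    regenerated until no spurious exact motif remains.
    """
    a_off = length - 1 - bp_dist
    m_start = a_off - 5
    for _ in range(200):
        seq = list(_random_seq(rng, length))
        seq[:6] = "GTATGT"
        seq[-2:] = "AG"
        seq[m_start : m_start + 7] = _BP_MOTIF
        s = "".join(seq)
        if s.count(_BP_MOTIF) == 1:
            return s, a_off
    raise RuntimeError("could not generate a unique-branchpoint intron")  # pragma: no cover


def simulate_annotation(config: SimulationConfig) -> tuple[str, str, list[GeneModel]]:
    """Build a synthetic chromosome: (GFF3 text, FASTA text, gene models).

    Genes are non-overlapping with >= 100 bp spacing, strands random.
    Intron-containing genes carry exon1|intron|exon2 with the planted branch
    motif; intronless genes are single exons.  Deterministic for a fixed
    config (identical seed => byte-identical files).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    n_ic = int(round(config.n_genes * config.intron_containing_fraction))
    classes = np.array([True] * n_ic + [False] * (config.n_genes - n_ic))
    rng.shuffle(classes)

    chrom_parts: list[str] = []
    genes: list[GeneModel] = []
    gff = ["##gff-version 3"]
    cursor = 0
    for idx, is_ic in enumerate(classes):
        gap = int(rng.integers(*config.intergenic_spacing, endpoint=True))
        chrom_parts.append(_random_seq(rng, gap))
        cursor += gap
        gene_id = f"g{idx + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        a_off = None
        if is_ic:
            e1 = int(rng.integers(*config.exon1_length, endpoint=True))
            il = int(rng.integers(*config.intron_length, endpoint=True))
            e2 = int(rng.integers(*config.exon2_length, endpoint=True))
            bp_dist = int(rng.integers(*config.bp_distance_to_3ss, endpoint=True))
            intron_seq, a_off = _make_intron_seq(rng, il, bp_dist)
            tx_seq = _random_seq(rng, e1) + intron_seq + _random_seq(rng, e2)
            glen = e1 + il + e2
            if strand == "+":
                exons = [(cursor, cursor + e1), (cursor + e1 + il, cursor + glen)]
            else:
                # transcript runs right-to-left: exon1 occupies the high end
                exons = [(cursor, cursor + e2), (cursor + e2 + il, cursor + glen)]
        else:
            glen = int(rng.integers(*config.intronless_length, endpoint=True))
            tx_seq = _random_seq(rng, glen)
            exons = [(cursor, cursor + glen)]
        chrom_parts.append(tx_seq if strand == "+" else _revcomp(tx_seq))
        gm = GeneModel.from_exons(gene_id, config.chrom_name, strand, exons)
        if a_off is not None:
            # record the planted branch A so the truth table is exact
            fi = gm.first_intron
            fi.bp = fi.five_ss + a_off if strand == "+" else fi.five_ss - a_off
            fi.bp_source = "planted"
        genes.append(gm)
        gff.append(
            f"{config.chrom_name}\tsim\tgene\t{cursor + 1}\t{cursor + glen}\t.\t{strand}\t.\tID={gene_id}"
        )
        gff.append(
            f"{config.chrom_name}\tsim\tmRNA\t{cursor + 1}\t{cursor + glen}\t.\t{strand}\t.\t"
            f"ID={gene_id}.t1;Parent={gene_id}"
        )
        for i, (s, e) in enumerate(sorted(exons)):
            gff.append(
                f"{config.chrom_name}\tsim\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                f"ID={gene_id}.t1.e{i + 1};Parent={gene_id}.t1"
            )
        cursor += glen
    tail = int(rng.integers(*config.intergenic_spacing, endpoint=True))
    chrom_parts.append(_random_seq(rng, tail))
    cursor += tail

    if config.chrom_length is not None:
        if cursor > config.chrom_length:
            raise CapacityError(
                f"genes need {cursor} bp but chrom_length is {config.chrom_length}"
            )
        chrom_parts.append(_random_seq(rng, config.chrom_length - cursor))
        cursor = config.chrom_length

    seq = "".join(chrom_parts)
    fasta_lines = [f">{config.chrom_name}"]
    fasta_lines += [seq[i : i + 70] for i in range(0, len(seq), 70)]
    return "\n".join(gff) + "\n", "\n".join(fasta_lines) + "\n", genes


def planted_truth(genes: list[GeneModel], config: SimulationConfig) -> TruthTable:
    """Truth table for a gene set: where the mutant stall was applied.

    The stall spans the 5'SS to the branch A (or the whole intron when
    ``stall_region='intron'``).  Gene models straight out of
    :func:`simulate_annotation` carry the planted branch A, so the region is
    exact; for bp-less models the midpoint of the configured BP distance band
    is used instead.
    """
    records = []
    stalled = config.stall_fold != 1.0
    for g in genes:
        if not g.introns:
            records.append(TruthRecord(g.gene_id, "intronless", False, -1, -1, 1.0))
            continue
        s, e = _stall_interval(g, config)
        records.append(
            TruthRecord(g.gene_id, "intron_containing", stalled, s, e, config.stall_fold)
        )
    return TruthTable(records)


def _stall_interval(gene: GeneModel, config: SimulationConfig) -> tuple[int, int]:
    """Genomic half-open stall interval for one intron-containing gene."""
    fi = gene.first_intron
    gs, ge = fi.genomic_interval()
    if config.stall_region == "intron":
        return gs, ge
    # 5'SS to the planted branch A; its distance to the 3'SS is deterministic
    # given the intron but was drawn at annotation time, so recover it from
    # the known BP if set, else use the midpoint of the configured band.
    if fi.bp is not None:
        lo, hi = sorted((fi.five_ss, fi.bp))
        return lo, hi + 1
    dist = int(round(sum(config.bp_distance_to_3ss) / 2))
    bp = fi.three_ss - dist if gene.strand == "+" else fi.three_ss + dist
    lo, hi = sorted((fi.five_ss, bp))
    return lo, hi + 1


def expected_coverage(
    genes: list[GeneModel],
    truth: TruthTable,
    config: SimulationConfig,
    condition: str,
    chrom_length: int,
) -> np.ndarray:
    """Expected per-base occupancy lambda(x) for one condition."""
    if condition not in ("wt", "mutant"):
        raise ValueError("condition must be 'wt' or 'mutant'")
    lam = np.full(chrom_length, config.background, dtype=np.float64)
    stall_of = {r.gene_id: (r.stall_start, r.stall_end) for r in truth.records if r.stalled}
    for g in genes:
        s, e = g.span
        lam[s:e] = config.baseline_occupancy
        # 5' occupancy peak (both conditions)
        if g.strand == "+":
            ps, pe = g.tss, min(g.tss + config.five_prime_peak_span, e)
        else:
            ps, pe = max(g.tss + 1 - config.five_prime_peak_span, s), g.tss + 1
        lam[ps:pe] *= config.five_prime_peak_fold
        if condition == "mutant" and g.introns:
            if g.gene_id in stall_of:
                ss, se = stall_of[g.gene_id]
                lam[ss:se] *= config.stall_fold
            # reduced elongation past the 3'SS
            fi = g.first_intron
            if g.strand == "+":
                ds, de = fi.three_ss + 1, e
            else:
                ds, de = s, fi.three_ss
            lam[ds:de] *= 1.0 - config.post_3ss_drop
    return lam


def simulate_coverage(
    genes: list[GeneModel],
    truth: TruthTable,
    config: SimulationConfig,
    condition: str,
    chrom_length: int,
) -> CoverageTrack:
    """Draw a Poisson per-base coverage track for one condition.

    total_mapped_reads is set to the read count a ``read_length``-base
    single-end library of this depth implies (sum of counts / read length).
    """
    lam = expected_coverage(genes, truth, config, condition, chrom_length)
    cond_idx = {"wt": 1, "mutant": 2}[condition]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, cond_idx]))
    counts = rng.poisson(lam).astype(np.float64)
    total = max(1, int(round(counts.sum() / config.read_length)))
    return CoverageTrack(
        values={config.chrom_name: counts},
        value_kind="raw_counts",
        total_mapped_reads=total,
        source_label=condition,
    )


def simulate_reads_bam(
    genes: list[GeneModel],
    truth: TruthTable,
    config: SimulationConfig,
    condition: str,
    chrom_length: int,
    bam_path: str,
) -> int:
    """Emit a sorted+indexed BAM of 50-base synthetic reads for one condition.

    The start-count at each position is drawn Poisson with rate set by the
    expected coverage at the read *midpoint* divided by the read length, so
    the pileup of the BAM is an unbiased, read-length-smoothed realization
    of the same expected coverage as the per-base track.  Returns the number
    of reads written.
    """
    lam = expected_coverage(genes, truth, config, condition, chrom_length)
    cond_idx = {"wt": 3, "mutant": 4}[condition]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, cond_idx]))
    rl = config.read_length
    max_start = chrom_length - rl
    midpoints = np.arange(max_start + 1) + rl // 2
    n_starts = rng.poisson(lam[midpoints] / rl)
    starts = np.repeat(np.arange(max_start + 1), n_starts)

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": config.chrom_name, "LN": chrom_length}],
    }
    with pysam.AlignmentFile(bam_path, "wb", header=header) as bam:
        for i, start in enumerate(starts):
            a = pysam.AlignedSegment(bam.header)
            a.query_name = f"{condition}_read_{i}"
            a.query_sequence = "A" * rl
            a.reference_id = 0
            a.reference_start = int(start)
            a.mapping_quality = 60
            a.cigartuples = [(0, rl)]
            a.flag = 0
            bam.write(a)
    pysam.index(bam_path)
    return len(starts)


@dataclass
class FixtureBundle:
    """All files + in-memory objects for one end-to-end synthetic run."""

    config: SimulationConfig
    genes: list[GeneModel]
    truth: TruthTable
    chrom_length: int
    gff3: str
    fasta: str
    wt_bedgraph: str
    mutant_bedgraph: str
    wt_bam: str
    mutant_bam: str
    truth_tsv: str


def end_to_end_fixture(config: SimulationConfig, out_dir: str) -> FixtureBundle:
    """Generate the full file bundle the pipeline consumes, plus truth.

    Writes GFF3, genome FASTA, wt/mutant bedGraph coverage (with
    ``#total_mapped`` headers), wt/mutant BAM (+ index) and the truth TSV.
    """
    from .coverage import write_bedgraph

    config.validate()
    os.makedirs(out_dir, exist_ok=True)
    gff3_text, fasta_text, genes = simulate_annotation(config)
    chrom_length = sum(len(l) for l in fasta_text.splitlines()[1:])
    truth = planted_truth(genes, config)

    paths = {
        "gff3": os.path.join(out_dir, "annotation.gff3"),
        "fasta": os.path.join(out_dir, "genome.fa"),
        "wt_bedgraph": os.path.join(out_dir, "wt.bedgraph"),
        "mutant_bedgraph": os.path.join(out_dir, "mutant.bedgraph"),
        "wt_bam": os.path.join(out_dir, "wt.bam"),
        "mutant_bam": os.path.join(out_dir, "mutant.bam"),
        "truth_tsv": os.path.join(out_dir, "truth.tsv"),
    }
    with open(paths["gff3"], "w") as fh:
        fh.write(gff3_text)
    with open(paths["fasta"], "w") as fh:
        fh.write(fasta_text)
    for cond, key in (("wt", "wt_bedgraph"), ("mutant", "mutant_bedgraph")):
        track = simulate_coverage(genes, truth, config, cond, chrom_length)
        write_bedgraph(track, paths[key])
    for cond, key in (("wt", "wt_bam"), ("mutant", "mutant_bam")):
        simulate_reads_bam(genes, truth, config, cond, chrom_length, paths[key])
    truth.to_tsv(paths["truth_tsv"])
    return FixtureBundle(
        config=config,
        genes=genes,
        truth=truth,
        chrom_length=chrom_length,
        gff3=paths["gff3"],
        fasta=paths["fasta"],
        wt_bedgraph=paths["wt_bedgraph"],
        mutant_bedgraph=paths["mutant_bedgraph"],
        wt_bam=paths["wt_bam"],
        mutant_bam=paths["mutant_bam"],
        truth_tsv=paths["truth_tsv"],
    )


def null_config(config: SimulationConfig | None = None) -> SimulationConfig:
    """The matched no-stall control: identical expected coverage in both
    conditions (stall fold 1, no post-3'SS drop)."""
    return replace(config or SimulationConfig(), stall_fold=1.0, post_3ss_drop=0.0)


def score_against_truth(gene_calls, truth: TruthTable) -> tuple[float, float]:
    """(sensitivity, specificity) of enriched-gene calls vs planted stalls."""
    stalled = truth.stalled_ids()
    called = {c.gene_id for c in gene_calls if c.enriched}
    all_ids = {r.gene_id for r in truth.records}
    tp = len(stalled & called)
    fp = len(called - stalled)
    tn = len(all_ids - stalled - called)
    sensitivity = tp / len(stalled) if stalled else float("nan")
    negatives = len(all_ids - stalled)
    specificity = tn / negatives if negatives else float("nan")
    return sensitivity, specificity
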