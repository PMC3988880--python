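"""Detect intronic Pol II stalling in a two-condition synthetic study.

Generates the default synthetic genome (200 genes, 5% intron-containing)
with a planted 4-fold mutant-only occupancy stall between each intron's 5'
splice site and branchpoint, then runs the full enrichment pipeline and
scores the calls against the planted truth.
"""

import tempfile

import intronstall as it

cfg = it.SimulationConfig(seed=7)
with tempfile.TemporaryDirectory() as workdir:
    bundle = it.end_to_end_fixture(cfg, workdir)
    genes = it.load_annotation(bundle.gff3)
    wt = it.normalize(it.read_bedgraph(bundle.wt_bedgraph, source_label="WT25"))
    mt = it.normalize(it.read_bedgraph(bundle.mutant_bedgraph, source_label="MT37"))

    ratio = it.ratio_track(mt, wt, pseudocount=1.0)
    partition = it.feature_partition(genes, {cfg.chrom_name: bundle.chrom_length})
    report = it.enrichment_report(ratio, partition, genes, threshold=2.0, min_run=10)
    sens, spec = it.score_against_truth(report.gene_calls, bundle.truth)

print("Fraction of bases enriched >2-fold (mutant/WT), by feature class:")
for name, frac in report.class_fractions.items():
    print(f"  {name:>10}: {100 * frac:5.1f}%")
print(f"Genes with an enriched region (>=10 consecutive bases): {report.n_enriched_genes}")
print(f"Sensitivity vs planted stalls: {sens:.2f}   specificity: {spec:.2f}")
print()
print("Introns dominate the enriched bases because the planted stall is")
print("intron-restricted; flat classes sit near the false-positive floor.")
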