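# Methods

## Problem and model

Cotranscriptional spliceosome assembly can gate transcription elongation:
when prespliceosome formation fails, RNA polymerase II accumulates over the
introns it is transcribing.  In ChIP-seq terms this appears as a localized
excess of mutant-condition coverage over wild-type coverage between the 5'
splice site and the branchpoint, followed by a coverage *deficit* past the
3' splice site (fewer polymerases make it into exon2).  The pipeline
formalizes that signature as per-base fold enrichment between two
depth-normalized coverage tracks, summarized three ways: enriched-base
fractions per feature class, per-gene enriched-region calls, and
splice-feature-anchored metaprofiles.

## Coordinate and anatomy conventions

Internally all coordinates are 0-based; intervals are half-open, anchor
points (TSS, 5'SS, BP, 3'SS, 3' end) are single-base positions.  GFF3/GTF
and branchpoint-table I/O convert from 1-based closed coordinates at the
boundary.  One transcript per gene is analyzed (the longest).  The feature
vocabulary assumes the yeast regime of a single 5'-proximal intron: *exon1*
is the exon upstream of the **first** intron, *exon2* is all exonic
sequence downstream of it, and additional introns of multi-intron genes
count as *intron*.  Bases covered by overlapping genes of conflicting class
are dropped from all totals by default (`drop_conflicts`); an alternative
policy lets intron-containing-gene classes override intronless overlap.
Genes spanning under 200 bp are excluded at load time.

## Coverage and normalization

Reads with MAPQ ≥ 20 are counted over their full aligned reference span
(CIGAR M/D/=/X; spliced N gaps uncovered); mates are counted independently
and duplicates retained by default.  No fragment extension or shifting is
applied (a fixed-length extension is available but off).  Depth
normalization is reads per million mapped (RPM).  bedGraph I/O is exact
run-length encoding carrying `#total_mapped=` and `#chrom_lengths=`
headers so a track round-trips losslessly.

## Enrichment

The ratio track is `(num + c)/(den + c)` with pseudocount `c = 1` RPM on
both sides — enough to suppress division blow-ups at near-zero coverage
without masking genuine multi-fold signals at typical depths.  A base is
enriched when the ratio strictly exceeds the fold threshold (default 2; a
non-strict flag exists).  Class fractions are computed at base resolution
with no smoothing; a class with zero bases reports "undefined" rather
than 0.  Gene calls require ≥ `min_run` = 10 consecutive enriched bases
within the gene body — long enough that isolated Poisson flickers (which
occur per base at rates ≪ 1%) essentially never chain into a false call,
short enough that any biologically sized stall (tens of bases) is kept.

## Branchpoint localization

When no curated table is supplied, the branch adenosine is located by
scanning the intron (5'→3') for the *S. cerevisiae* consensus `TACTAAC`,
allowing ≤ 1 mismatch but never at the branch A itself; candidates must
place the branch A 5–200 nt upstream of the 3'SS, and ties are broken
toward the 3'SS (where functional yeast branchpoints sit).  Assignment
provenance (`table` / `motif` / `none`) is recorded per intron; genes with
unknown BP are excluded only from BP-anchored profiles, never from the
partition or gene calls.

## Metaprofiles

Proximity profiles average track values at signed offsets (default window
±200 bases) from an anchor in transcript orientation, with per-offset gene
counts so chromosome-edge truncation does not bias means; genes are
weighted equally.  Ratio profiles divide two mean curves per offset
(ratio of means — the ratio of the two plotted averages — not the mean of
per-gene ratios).  Scaled profiles cut the segments (up to 100 bp upstream
of the 5'SS, truncated to exon1 when shorter; the intron; 3'SS to 3' end)
into (10, 20, 20) equal-length bins per gene before averaging, making
genes of different intron lengths comparable; with piecewise-constant
coverage the result is invariant to stretching intron lengths.

## Region significance

For a named region (feature class or anchor ± window) the per-gene mean
RPM is computed in each condition and the paired differences tested
two-sided: Wilcoxon signed-rank (≥ 5 genes; identical conditions return
p = 1 by convention) or a sign-flip permutation of the mean difference
(default 10,000 permutations, seeded, add-one p-value).  Both are
distribution-free and paired; the signed-rank is the default.

## Synthetic data

The generator encodes the study conditions: 200 genes, 5% intron
containing (the yeast census), exon1 100–300 bp, introns 100–400 bp with
the branch A planted 20–60 nt upstream of the 3'SS (unique exact `TACTAAC`
per intron; `GTATGT`…`AG` termini), exon2 300–800 bp, intronless genes
0.5–1.5 kb, ≥ 100 bp intergenic spacing, random strands on one synthetic
chromosome (~0.2 Mb).  Expected occupancy is multiplicative: background 1
(5% of the gene-body depth), gene-body baseline 20, a 3-fold 5' peak over
the first 100 bases (both conditions, mimicking the 5'-biased initiation
signal), and in the mutant only a stall fold (default 4) over the
5'SS-to-BP segment plus a post-3'SS drop (default 30%).  Counts are
independent Poisson per base; a matched read-level BAM draws 50-base read
starts at rate λ(midpoint)/50, so its pileup is an unbiased read-length-
smoothed realization of the same expected coverage.  The per-base Pearson
correlation between pileup and the (independently drawn) count track is
therefore bounded by the shared-signal fraction var(λ)/(var(λ)+mean(λ)) —
about 0.9 at depth 20 — and the consistency test instead checks the pileup
against the smoothed λ plus segment-mean recovery within 3 standard
errors.  The stall fold of 4 is a testability choice, not a measured
value; the null configuration (`null_config`) sets stall fold 1 *and* drop
0 so both conditions share an identical expected track.  Identical
config + seed gives byte-identical outputs.

What the simulation does **not** model: mappability and GC bias,
overdispersion beyond Poisson, fragment-size variation, antibody-specific
(pSer5/pSer2) channels, alternative isoforms, or condition-dependent
expression changes outside the planted stall/drop.  Passing tests
therefore demonstrate correctness of the computations and recoverability
of an intron-restricted signal under clean noise — not robustness to
real-library artifacts.

## Problem sizes and determinism

Tests and the acceptance script run the default 200-gene, ~0.2 Mb study —
large enough for ~10 intron-containing genes and stable Poisson means,
small enough to regenerate in seconds.  All randomness flows through
numpy `SeedSequence`s derived from a single integer seed (annotation,
each condition's track, and each condition's reads use separate streams),
and the permutation test takes its own seed.

## Known limitations

- The exon1/intron/exon2 split presumes the first intron is the relevant
  one; deep multi-intron genomes would need a per-intron generalization.
- `total_mapped_reads` for simulated tracks is derived as
  (total counts / read length), the read count such a library implies.
- The paired region test treats genes as exchangeable units; strong
  gene-length or expression confounding between conditions would call for
  a covariate-adjusted model instead.
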