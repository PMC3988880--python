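"""Anchored metagene profiles, scaled binned profiles, and a region test.

Proximity profiles average per-base coverage across genes as a function of
signed distance from one of five anchors (TSS, 5'SS, BP, 3'SS, 3' end), in
transcript orientation: positive offsets are always downstream, so minus-
strand genes are read right-to-left.  Scaled profiles instead divide the
segments between anchors (100 bp upstream of the 5'SS, the intron, exon2)
into fixed bin counts so genes of different lengths average bin-wise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    EmptyProfileError,
    InsufficientDataError,
    ShapeMismatchError,
)
from .models import (
    ANCHORS,
    CoverageTrack,
    GeneModel,
    MetaProfile,
    ScaledProfile,
    tx_shift,
)

logger = logging.getLogger(__name__)


def proximity_profile(
    track: CoverageTrack,
    genes: list[GeneModel],
    anchor: str,
    window: int = 200,
) -> MetaProfile:
    """Gene-averaged coverage at offsets [-window, +window] around an anchor.

    Genes lacking the anchor (e.g. unknown BP for BP-anchored profiles) are
    excluded and logged.  Offsets that fall off the chromosome do not
    contribute, and per-offset gene counts are tracked so means stay unbiased
    at the edges.
    """
    if anchor not in ANCHORS:
        raise ValueError(f"anchor must be one of {ANCHORS}")
    if window < 1:
        raise ValueError("window must be >= 1")
    offsets = np.arange(-window, window + 1)
    sums = np.zeros_like(offsets, dtype=np.float64)
    counts = np.zeros_like(offsets, dtype=np.int64)
    n_excluded = 0
    for gene in genes:
        pos0 = gene.anchor_position(anchor)
        if pos0 is None:
            n_excluded += 1
            continue
        arr = track.values[gene.chrom]
        positions = tx_shift(pos0, offsets, gene.strand)
        valid = (positions >= 0) & (positions < len(arr))
        sums[valid] += arr[positions[valid]]
        counts[valid] += 1
    if counts.max(initial=0) == 0:
        raise EmptyProfileError(f"no gene provides the {anchor} anchor")
    if n_excluded:
        logger.info("proximity_profile(%s): %d gene(s) lacked the anchor", anchor, n_excluded)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return MetaProfile(anchor=anchor, offsets=offsets, mean_value=mean, n_genes=counts, value_kind="rpm")


def ratio_profile(
    numerator_profile: MetaProfile,
    denominator_profile: MetaProfile,
    pseudocount: float = 0.0,
) -> MetaProfile:
    """Per-offset ratio of two gene-averaged profiles (ratio of means).

    This matches taking the ratio of two plotted mean curves, not the mean of
    per-gene ratios.  Both profiles must share anchor, offsets and gene sets.
    """
    a, b = numerator_profile, denominator_profile
    if a.anchor != b.anchor or not np.array_equal(a.offsets, b.offsets):
        raise ShapeMismatchError("profiles differ in anchor or offsets")
    if not np.array_equal(a.n_genes, b.n_genes):
        raise ShapeMismatchError("profiles were built from different gene sets")
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = (a.mean_value + pseudocount) / (b.mean_value + pseudocount)
    return MetaProfile(
        anchor=a.anchor,
        offsets=a.offsets.copy(),
        mean_value=mean,
        n_genes=a.n_genes.copy(),
        value_kind="ratio",
    )


def _tx_values(track: CoverageTrack, gene: GeneModel, start: int, end_inclusive: int) -> np.ndarray:
    """Track values from start..end_inclusive walking downstream in tx sense."""
    arr = track.values[gene.chrom]
    if gene.strand == "+":
        return arr[start : end_inclusive + 1]
    return arr[end_inclusive : start + 1][::-1]


def _bin_means(vals: np.ndarray, n_bins: int) -> np.ndarray:
    """Mean of n_bins equal-length windows; short segments reuse bases."""
    L = len(vals)
    bounds = np.floor(np.linspace(0, L, n_bins + 1)).astype(int)
    out = np.empty(n_bins)
    for j in range(n_bins):
        s, e = bounds[j], bounds[j + 1]
        if e <= s:  # more bins than bases: repeat the nearest base
            s = min(s, L - 1)
            e = s + 1
        out[j] = vals[s:e].mean()
    return out


@dataclass
class ScaledProfileConfig:
    bins_per_segment: tuple[int, int, int] = (10, 20, 20)
    upstream: int = 100  # bases upstream of the 5'SS in the first segment


def scaled_profile(
    track: CoverageTrack,
    genes: list[GeneModel],
    config: ScaledProfileConfig | None = None,
) -> ScaledProfile:
    """Length-normalized binned profile over (upstream-of-5'SS, intron, exon2).

    Each intron-containing gene contributes one value per bin: its segment is
    cut into the configured number of equal-length windows and the per-window
    mean coverage averaged across genes.  Genes whose first exon is shorter
    than the upstream span use all available exon1 bases (at least 1); the
    truncation is logged.
    """
    config = config or ScaledProfileConfig()
    nb = config.bins_per_segment
    eligible = [g for g in genes if g.introns]
    if not eligible:
        raise EmptyProfileError("no intron-containing genes for scaled profile")
    sums = np.zeros(sum(nb))
    n_short = 0
    for gene in eligible:
        fi = gene.first_intron
        exon1_len = gene.exons[0][1] - gene.exons[0][0]
        up = min(config.upstream, max(exon1_len, 1))
        if up < config.upstream:
            n_short += 1
        # upstream segment ends at the base immediately 5' of the 5'SS
        up_end = tx_shift(fi.five_ss, -1, gene.strand)
        up_start = tx_shift(fi.five_ss, -up, gene.strand)
        segs = [
            _tx_values(track, gene, up_start, up_end),
            _tx_values(track, gene, fi.five_ss, fi.three_ss),
            _tx_values(track, gene, tx_shift(fi.three_ss, 1, gene.strand), gene.three_prime_end),
        ]
        sums += np.concatenate([_bin_means(v, n) for v, n in zip(segs, nb)])
    if n_short:
        logger.info("scaled_profile: %d gene(s) had exon1 < %d bp; truncated", n_short, config.upstream)
    return ScaledProfile(
        segment_labels=("upstream", "intron", "exon2"),
        bins_per_segment=nb,
        mean_value=sums / len(eligible),
        n_genes=len(eligible),
    )


@dataclass
class RegionTestResult:
    p_value: float
    method: str
    n_genes: int
    statistic: float
    table: pd.DataFrame  # gene_id, mean_a, mean_b, diff


def _region_positions(gene: GeneModel, region) -> np.ndarray | None:
    """Genomic positions of a named region within one gene, or None."""
    if isinstance(region, tuple):  # (anchor, window)
        anchor, window = region
        pos0 = gene.anchor_position(anchor)
        if pos0 is None:
            return None
        return tx_shift(pos0, np.arange(-window, window + 1), gene.strand)
    if region == "gene":
        s, e = gene.span
        return np.arange(s, e)
    code_of = {"exon1": 1, "intron": 2, "exon2": 3}
    if region not in code_of:
        raise ValueError(f"unknown region {region!r}")
    wanted = code_of[region]
    chunks = [np.arange(s, e) for (s, e, code) in gene.feature_intervals() if code == wanted]
    if not chunks:
        return None
    return np.concatenate(chunks)


def region_test(
    track_a: CoverageTrack,
    track_b: CoverageTrack,
    genes: list[GeneModel],
    region="intron",
    method: str = "wilcoxon",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> RegionTestResult:
    """Paired per-gene test of condition A vs B coverage over a region.

    ``region`` is a feature class ('exon1'|'intron'|'exon2'|'gene') or an
    (anchor, window) tuple.  For each eligible gene the mean RPM over the
    region is computed in both conditions; 'wilcoxon' (alias 'mannwhitney')
    runs a two-sided Wilcoxon signed-rank on the paired means, 'permutation'
    a label-swap (sign-flip) null of the mean paired difference.
    """
    if method == "mannwhitney":
        method = "wilcoxon"
    if method not in ("wilcoxon", "permutation"):
        raise ValueError(f"unknown method {method!r}")
    rows = []
    for gene in genes:
        positions = _region_positions(gene, region)
        if positions is None:
            continue
        arr_a, arr_b = track_a.values[gene.chrom], track_b.values[gene.chrom]
        ok = (positions >= 0) & (positions < len(arr_a))
        positions = positions[ok]
        if positions.size == 0:
            continue
        rows.append((gene.gene_id, float(arr_a[positions].mean()), float(arr_b[positions].mean())))
    n = len(rows)
    if method == "wilcoxon" and n < 5:
        raise InsufficientDataError(f"wilcoxon needs >= 5 genes, got {n}")
    if method == "permutation" and n_permutations < 1000:
        raise InsufficientDataError("permutation test needs >= 1000 permutations")
    if method == "permutation" and n == 0:
        raise InsufficientDataError("no eligible genes for region test")

    table = pd.DataFrame(rows, columns=["gene_id", "mean_a", "mean_b"])
    table["diff"] = table["mean_a"] - table["mean_b"]
    diffs = table["diff"].to_numpy()

    if method == "wilcoxon":
        if np.allclose(diffs, 0):
            p, stat = 1.0, 0.0  # degenerate: identical conditions
        else:
            res = stats.wilcoxon(diffs, alternative="two-sided")
            p, stat = float(res.pvalue), float(res.statistic)
    else:
        rng = np.random.default_rng(seed)
        observed = diffs.mean()
        signs = rng.choice((-1.0, 1.0), size=(n_permutations, n))
        null = (signs * diffs).mean(axis=1)
        p = float((1 + np.count_nonzero(np.abs(null) >= abs(observed))) / (n_permutations + 1))
        stat = float(observed)
    return RegionTestResult(p_value=p, method=method, n_genes=n, statistic=stat, table=table)


def profile_to_tsv(profile: MetaProfile, path: str) -> None:
    pd.DataFrame(
        {"offset": profile.offsets, "mean": profile.mean_value, "n_genes": profile.n_genes}
    ).to_csv(path, sep="\t", index=False)
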