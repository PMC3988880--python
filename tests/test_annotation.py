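"""Gene-model parsing, branchpoint scanning and the feature partition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import intronstall as it
from intronstall.annotation import BPParams
from intronstall.exceptions import AnnotationError, EmptyPartitionError
from intronstall.models import CLASS_CODES

from conftest import mirror_genes


GFF_HEADER = "##gff-version 3\n"


def write_gff(tmp_path, body, name="test.gff3"):
    p = tmp_path / name
    p.write_text(GFF_HEADER + body)
    return str(p)


class TestLoadAnnotation:
    def test_two_exon_transcript_yields_one_intron(self, tmp_path):
        path = write_gff(
            tmp_path,
            "chrT\tx\tgene\t1\t600\t.\t+\t.\tID=gA\n"
            "chrT\tx\tmRNA\t1\t600\t.\t+\t.\tID=gA.t1;Parent=gA\n"
            "chrT\tx\texon\t1\t100\t.\t+\t.\tID=e1;Parent=gA.t1\n"
            "chrT\tx\texon\t301\t600\t.\t+\t.\tID=e2;Parent=gA.t1\n",
        )
        (g,) = it.load_annotation(path)
        assert g.gene_class == "intron_containing"
        assert g.exons == [(0, 100), (300, 600)]
        (intron,) = g.introns
        assert (intron.five_ss, intron.three_ss) == (100, 299)
        assert (g.tss, g.three_prime_end) == (0, 599)

    def test_single_exon_transcript_is_intronless(self, tmp_path):
        path = write_gff(
            tmp_path,
            "chrT\tx\tgene\t1\t500\t.\t+\t.\tID=gB\n"
            "chrT\tx\tmRNA\t1\t500\t.\t+\t.\tID=gB.t1;Parent=gB\n"
            "chrT\tx\texon\t1\t500\t.\t+\t.\tID=e1;Parent=gB.t1\n",
        )
        (g,) = it.load_annotation(path)
        assert g.gene_class == "intronless"
        assert g.introns == []

    def test_minus_strand_mirrors_plus_strand(self, tmp_path):
        """5'SS/3'SS on a - strand transcript are the genomic mirror image."""
        path = write_gff(
            tmp_path,
            "chrT\tx\tgene\t1\t600\t.\t-\t.\tID=gC\n"
            "chrT\tx\tmRNA\t1\t600\t.\t-\t.\tID=gC.t1;Parent=gC\n"
            "chrT\tx\texon\t1\t100\t.\t-\t.\tID=e1;Parent=gC.t1\n"
            "chrT\tx\texon\t301\t600\t.\t-\t.\tID=e2;Parent=gC.t1\n",
        )
        (g,) = it.load_annotation(path)
        # transcript order: high-coordinate exon first
        assert g.exons == [(300, 600), (0, 100)]
        (intron,) = g.introns
        # brute-force mirror of the + strand case on a 600 bp span:
        # + strand had five_ss=100, three_ss=299 -> reflected: 599-100, 599-299
        assert (intron.five_ss, intron.three_ss) == (599 - 300, 599 - 499)
        assert (g.tss, g.three_prime_end) == (599, 0)

    def test_overlapping_exons_are_skipped(self, tmp_path):
        path = write_gff(
            tmp_path,
            "chrT\tx\tgene\t1\t600\t.\t+\t.\tID=gD\n"
            "chrT\tx\tmRNA\t1\t600\t.\t+\t.\tID=gD.t1;Parent=gD\n"
            "chrT\tx\texon\t1\t200\t.\t+\t.\tID=e1;Parent=gD.t1\n"
            "chrT\tx\texon\t150\t600\t.\t+\t.\tID=e2;Parent=gD.t1\n"
            "chrT\tx\tgene\t701\t1300\t.\t+\t.\tID=gE\n"
            "chrT\tx\tmRNA\t701\t1300\t.\t+\t.\tID=gE.t1;Parent=gE\n"
            "chrT\tx\texon\t701\t1300\t.\t+\t.\tID=e3;Parent=gE.t1\n",
        )
        genes = it.load_annotation(path)
        assert [g.gene_id for g in genes] == ["gE"]

    def test_unparseable_file_raises_format_error(self, tmp_path):
        p = tmp_path / "junk.gff3"
        p.write_text("this is not an annotation\nat all\n")
        with pytest.raises(AnnotationError):
            it.load_annotation(str(p))

    def test_min_length_filter(self, tmp_path):
        path = write_gff(
            tmp_path,
            "chrT\tx\tgene\t1\t150\t.\t+\t.\tID=gS\n"
            "chrT\tx\tmRNA\t1\t150\t.\t+\t.\tID=gS.t1;Parent=gS\n"
            "chrT\tx\texon\t1\t150\t.\t+\t.\tID=e1;Parent=gS.t1\n",
        )
        assert it.load_annotation(path) == []
        cfg = it.AnnotationConfig(min_gene_length=100)
        assert len(it.load_annotation(path, cfg)) == 1


def _brute_best_bp(seq, params):
    """Exhaustive scan used as the independent oracle for find_branchpoint."""
    motif, k = params.motif, len(params.motif)
    cands = []
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        mm = sum(a != b for a, b in zip(w, motif))
        if w[params.branch_index] != motif[params.branch_index]:
            continue
        if mm > params.max_mismatch:
            continue
        a_off = i + params.branch_index
        dist = len(seq) - 1 - a_off
        if params.min_dist_3ss <= dist <= params.max_dist_3ss:
            cands.append((mm, dist, a_off))
    return min(cands)[2] if cands else None


class TestFindBranchpoint:
    def test_unique_exact_match(self):
        # single exact motif, branch A 43 nt upstream of the last intronic base
        seq = "GTATGT" + "C" * 50 + "TACTAAC" + "G" * 40 + "AG"
        a_off = 6 + 50 + 5
        assert len(seq) - 1 - a_off == 43
        assert it.find_branchpoint(seq) == a_off

    def test_tie_break_prefers_match_nearest_3ss(self):
        """Two exact motifs: the one closer to the 3'SS wins."""
        seq = "G" * 30 + "TACTAAC" + "C" * 73 + "TACTAAC" + "T" * 35 + "AG"
        expected = _brute_best_bp(seq, BPParams())
        got = it.find_branchpoint(seq)
        assert got == expected
        # and it is the downstream copy
        assert got == 30 + 7 + 73 + 5

    def test_no_match_returns_unknown(self):
        assert it.find_branchpoint("G" * 120 + "AG") is None

    def test_branch_adenosine_never_mismatched(self):
        # TACTATC differs from the motif only at the branch A: not a hit
        seq = "C" * 60 + "TACTATC" + "G" * 40 + "AG"
        assert it.find_branchpoint(seq) is None

    def test_distance_bounds_respected(self):
        # branch A only 2 nt from the 3'SS: below the minimum distance
        seq = "C" * 100 + "TACTAAC" + "AG"
        assert it.find_branchpoint(seq) is None

    def test_non_nucleotide_characters_rejected(self):
        with pytest.raises(ValueError):
            it.find_branchpoint("ACGTXACGT" * 10)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=30, max_size=250))
    def test_matches_bruteforce_and_bounds_on_random_sequences(self, seq):
        params = BPParams()
        got = it.find_branchpoint(seq, params)
        assert got == _brute_best_bp(seq, params)
        if got is not None:
            dist = len(seq) - 1 - got
            assert params.min_dist_3ss <= dist <= params.max_dist_3ss
            assert seq[got] == "A"


class TestAttachBranchpoints:
    def _genes_with_fasta(self, tmp_path):
        cfg = it.SimulationConfig(n_genes=12, intron_containing_fraction=0.5, seed=5)
        gff3, fasta, genes = it.simulate_annotation(cfg)
        fa = tmp_path / "genome.fa"
        fa.write_text(fasta)
        gf = tmp_path / "genes.gff3"
        gf.write_text(gff3)
        return str(gf), str(fa), genes

    def test_sources_table_motif_none(self, tmp_path):
        import pandas as pd

        gff, fa, planted = self._genes_with_fasta(tmp_path)
        genes = it.load_annotation(gff)
        ic = [g for g in genes if g.introns]
        # table covers the first intron-containing gene only
        planted_bp = {g.gene_id: g.first_intron.bp for g in planted if g.introns}
        table = pd.DataFrame(
            [{"gene_id": ic[0].gene_id, "chrom": ic[0].chrom, "bp_position": planted_bp[ic[0].gene_id] + 1}]
        )
        it.attach_branchpoints(genes, bp_table=table, genome=fa)
        assert ic[0].first_intron.bp_source == "table"
        assert all(g.first_intron.bp_source == "motif" for g in ic[1:])
        # every assignment recovers the planted branch A exactly
        for g in ic:
            assert g.first_intron.bp == planted_bp[g.gene_id]

    def test_no_table_no_genome_leaves_all_unknown(self, tmp_path):
        gff, fa, _ = self._genes_with_fasta(tmp_path)
        genes = it.load_annotation(gff)
        it.attach_branchpoints(genes)
        assert all(
            i.bp is None and i.bp_source == "none" for g in genes for i in g.introns
        )

    def test_table_coordinate_on_splice_site_rejected(self, tmp_path):
        import pandas as pd

        gff, fa, _ = self._genes_with_fasta(tmp_path)
        genes = it.load_annotation(gff)
        ic = [g for g in genes if g.introns][0]
        table = pd.DataFrame(
            [{"gene_id": ic.gene_id, "chrom": ic.chrom, "bp_position": ic.first_intron.three_ss + 1}]
        )
        it.attach_branchpoints(genes, bp_table=table)  # no genome fallback
        assert ic.first_intron.bp is None
        assert ic.first_intron.bp_source == "none"


def brute_partition(genes, chrom_lengths, policy="drop_conflicts"):
    """Position-by-position classification: the independent oracle."""
    ic_codes = {1, 2, 3}
    maps = {c: np.zeros(n, dtype=np.int8) for c, n in chrom_lengths.items()}
    for g in genes:
        for (s, e, code) in g.feature_intervals():
            for p in range(s, e):
                cur = maps[g.chrom][p]
                if cur == 0:
                    maps[g.chrom][p] = code
                elif cur == code or cur == -1:
                    pass
                elif policy == "priority_intron_containing" and cur == 4 and code in ic_codes:
                    maps[g.chrom][p] = code
                elif policy == "priority_intron_containing" and code == 4 and cur in ic_codes:
                    pass
                else:
                    maps[g.chrom][p] = -1
    bases = {name: sum(int((m == c).sum()) for m in maps.values()) for name, c in CLASS_CODES.items()}
    total = sum(bases.values())
    return maps, bases, {k: v / total for k, v in bases.items()}


class TestFeaturePartition:
    def test_single_intronless_gene_is_all_intronless(self, chrom_lengths):
        g = it.GeneModel.from_exons("g", "chrT", "+", [(100, 600)])
        part = it.feature_partition([g], chrom_lengths)
        assert part.fractions == {"exon1": 0.0, "intron": 0.0, "exon2": 0.0, "intronless": 1.0}
        assert part.bases["intronless"] == 500

    def test_three_part_gene_fractions(self, chrom_lengths):
        # exon1 100 bp, intron 200 bp, exon2 300 bp -> 1/6, 1/3, 1/2
        g = it.GeneModel.from_exons("g", "chrT", "+", [(0, 100), (300, 600)])
        part = it.feature_partition([g], chrom_lengths)
        assert part.fractions["exon1"] == pytest.approx(1 / 6)
        assert part.fractions["intron"] == pytest.approx(1 / 3)
        assert part.fractions["exon2"] == pytest.approx(1 / 2)
        assert part.fractions["intronless"] == 0.0

    @pytest.mark.parametrize("policy", ["drop_conflicts", "priority_intron_containing"])
    def test_overlapping_genes_match_bruteforce(self, policy, chrom_lengths):
        ic = it.GeneModel.from_exons("ic", "chrT", "+", [(0, 100), (300, 600)])
        overlapping = it.GeneModel.from_exons("less", "chrT", "+", [(450, 900)])
        part = it.feature_partition([ic, overlapping], chrom_lengths, policy=policy)
        maps, bases, fracs = brute_partition([ic, overlapping], chrom_lengths, policy)
        assert part.bases == bases
        np.testing.assert_array_equal(part.class_map["chrT"], maps["chrT"])
        assert sum(part.fractions.values()) == pytest.approx(1.0, abs=1e-9)
        if policy == "drop_conflicts":
            assert part.dropped_bases == 150  # [450,600) covered by both

    def test_fractions_sum_to_one_on_simulated_annotation(self):
        cfg = it.SimulationConfig(n_genes=40, intron_containing_fraction=0.25, seed=3)
        _, fasta, genes = it.simulate_annotation(cfg)
        L = sum(len(l) for l in fasta.splitlines()[1:])
        part = it.feature_partition(genes, {cfg.chrom_name: L})
        assert sum(part.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_strand_mirror_preserves_class_totals(self):
        cfg = it.SimulationConfig(n_genes=40, intron_containing_fraction=0.25, seed=3)
        _, fasta, genes = it.simulate_annotation(cfg)
        L = sum(len(l) for l in fasta.splitlines()[1:])
        lengths = {cfg.chrom_name: L}
        part = it.feature_partition(genes, lengths)
        mirrored = it.feature_partition(mirror_genes(genes, lengths), lengths)
        assert part.bases == mirrored.bases

    def test_empty_gene_list_raises(self):
        with pytest.raises(EmptyPartitionError):
            it.feature_partition([])

    def test_bed_and_json_outputs(self, hand_genes, chrom_lengths):
        part = it.feature_partition(hand_genes, chrom_lengths)
        bed = it.partition_to_bed(hand_genes)
        assert "exon1" in bed and "intronless" in bed
        js = it.partition_summary_json(part)
        assert '"intron"' in js
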