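"""Coverage filters, locus spacing, and CDS alignment construction."""

import itertools

import pandas as pd
import pytest

from introgscan.orthologs import (
    CdsAlignment,
    GeneModel,
    alignment_passes_filters,
    build_cds_alignment,
    count_parsimony_informative_sites,
    enforce_min_spacing,
    filter_genes_by_coverage,
    read_gene_models,
)
from introgscan.variant_filters import GenotypeCall, SiteRecord


def _coverage(rows):
    return pd.DataFrame(rows, columns=["gene_id", "sample",
                                       "mean_depth", "frac_ge10"])


BASELINES = {"s1": 20.0, "s2": 25.0}


def _gene(gid="g1", chrom="c1", start=1, end=300):
    return GeneModel(gid, chrom, start, end, ((start, end),))


class TestCoverageFilter:
    def _run(self, rows):
        genes = [_gene()]
        return filter_genes_by_coverage(genes, _coverage(rows), BASELINES)

    def test_low_depth_in_one_sample_removes_gene(self):
        kept, reasons = self._run([
            ("g1", "s1", 9.9, 0.9), ("g1", "s2", 30.0, 0.9),
        ])
        assert not kept
        assert reasons["g1"] == "low_depth:s1"

    def test_depth_above_double_baseline_removes_gene(self):
        kept, reasons = self._run([
            ("g1", "s1", 15.0, 0.9), ("g1", "s2", 2.1 * 25.0, 0.9),
        ])
        assert not kept
        assert reasons["g1"].startswith("putative_duplication")

    def test_low_breadth_removes_gene(self):
        kept, reasons = self._run([
            ("g1", "s1", 15.0, 0.74), ("g1", "s2", 30.0, 0.9),
        ])
        assert reasons["g1"] == "low_breadth:s1"

    def test_exact_thresholds_pass(self):
        kept, reasons = self._run([
            ("g1", "s1", 10.0, 0.75), ("g1", "s2", 2.0 * 25.0, 0.75),
        ])
        assert [g.gene_id for g in kept] == ["g1"]
        assert not reasons

    def test_missing_summary_names_the_pair(self):
        with pytest.raises(KeyError, match="g1.*s2"):
            self._run([("g1", "s1", 15.0, 0.9)])


class TestSpacing:
    def test_greedy_scan_example(self):
        genes = [
            _gene("g1", "c1", 1, 1000),
            _gene("g2", "c1", 15_000, 16_000),
            _gene("g3", "c1", 40_000, 41_000),
        ]
        kept = enforce_min_spacing(genes, min_gap=20_000)
        assert [g.gene_id for g in kept] == ["g1", "g3"]
        # brute-force: adjacent kept genes satisfy the gap on each chrom
        for a, b in itertools.pairwise(kept):
            assert a.chrom != b.chrom or b.start - a.end >= 20_000

    def test_greedy_is_prefix_maximal(self):
        """Each dropped gene violates the gap against the last kept
        gene before it — the defining property of the greedy scan."""
        genes = [_gene(f"g{i}", "c1", 1 + i * 7000, 2000 + i * 7000)
                 for i in range(20)]
        kept = enforce_min_spacing(genes, min_gap=20_000)
        kept_ids = {g.gene_id for g in kept}
        last_end = None
        for g in genes:
            if g.gene_id in kept_ids:
                last_end = g.end
            else:
                assert last_end is not None
                assert g.start - last_end < 20_000

    def test_single_gene_per_chromosome_all_kept(self):
        genes = [_gene("g1", "c1"), _gene("g2", "c2"), _gene("g3", "c3")]
        assert enforce_min_spacing(genes) == genes

    def test_overlapping_second_gene_dropped(self):
        genes = [_gene("g1", "c1", 1, 500), _gene("g2", "c1", 300, 900)]
        kept = enforce_min_spacing(genes)
        assert [g.gene_id for g in kept] == ["g1"]

    def test_unsorted_input_raises(self):
        genes = [_gene("g1", "c1", 5000, 6000), _gene("g2", "c1", 1, 100)]
        with pytest.raises(ValueError):
            enforce_min_spacing(genes)


class TestBuildAlignment:
    GENE = GeneModel("g", "c1", 101, 130, ((101, 130),))
    REF = "ACGTACGTACGTACGTACGTACGTACGTAC"  # 30 bp
    SAMPLES = ["x", "y"]

    def _site(self, pos, ref, alts, gts):
        return SiteRecord(
            chrom="c1", pos=pos, ref=ref, alts=alts, qual=50.0,
            genotypes=[GenotypeCall(g) for g in gts],
        )

    def test_no_variants_reproduces_reference(self):
        aln = build_cds_alignment(self.GENE, self.REF, [], self.SAMPLES)
        assert aln.sequences == {"x": self.REF, "y": self.REF}

    def test_homozygous_snv_substituted_in_carrier_only(self):
        v = self._site(105, "A", ("G",), [(1, 1), (0, 0)])
        aln = build_cds_alignment(self.GENE, self.REF, [v], self.SAMPLES)
        assert aln.sequences["x"][4] == "G"
        assert aln.sequences["y"] == self.REF

    def test_heterozygous_snv_becomes_iupac(self):
        v = self._site(105, "A", ("G",), [(0, 1), (0, 0)])
        aln = build_cds_alignment(self.GENE, self.REF, [v], self.SAMPLES)
        assert aln.sequences["x"][4] == "R"  # A/G

    def test_deletion_gaps_columns_and_conserves_length(self):
        # REF[9:13] in gene coords = columns 9..12; deletion of 3 bp
        v = self._site(110, self.REF[9:13], (self.REF[9],),
                       [(1, 1), (0, 0)])
        aln = build_cds_alignment(self.GENE, self.REF, [v], self.SAMPLES)
        assert aln.sequences["x"][10:13] == "---"
        assert len(aln.sequences["x"]) == len(self.REF)

    def test_insertion_ignored(self):
        v = self._site(105, "A", ("ATTT",), [(1, 1), (0, 0)])
        aln = build_cds_alignment(self.GENE, self.REF, [v], self.SAMPLES)
        assert aln.sequences["x"] == self.REF

    def test_missing_genotype_keeps_reference_with_mask(self):
        v = self._site(105, "A", ("G",), [(-1, -1), (0, 0)])
        aln = build_cds_alignment(self.GENE, self.REF, [v], self.SAMPLES)
        assert aln.sequences["x"] == self.REF
        assert aln.mask["x"][4] == "N"

    def test_variant_outside_cds_ignored(self, caplog):
        v = self._site(500, "A", ("G",), [(1, 1), (0, 0)])
        aln = build_cds_alignment(self.GENE, self.REF, [v], self.SAMPLES)
        assert aln.sequences["x"] == self.REF


class TestInformativeSites:
    def _aln(self, cols):
        seqs = ["".join(c) for c in zip(*cols)]
        return CdsAlignment("g", {f"t{i}": s for i, s in enumerate(seqs)})

    @pytest.mark.parametrize("column,informative", [
        ("AAGG", True),
        ("AAAG", False),
        ("AAG-", False),
        ("AGCT", False),
        ("AARG", False),  # ambiguity treated as missing
        ("AAGGG", True),
        ("CCTT", True),
    ])
    def test_single_column_cases(self, column, informative):
        assert count_parsimony_informative_sites(
            self._aln([tuple(column)])
        ) == int(informative)

    def test_exhaustive_four_taxon_patterns(self):
        """All 6^4 columns over {A,C,G,T,-,N} against the definition."""
        n_checked = 0
        for col in itertools.product("ACGT-N", repeat=4):
            counts = {}
            for ch in col:
                if ch in "ACGT":
                    counts[ch] = counts.get(ch, 0) + 1
            expected = sum(1 for v in counts.values() if v >= 2) >= 2
            got = count_parsimony_informative_sites(self._aln([col]))
            assert got == int(expected), col
            n_checked += 1
        assert n_checked == 6 ** 4

    def test_empty_alignment_raises(self):
        with pytest.raises(ValueError):
            CdsAlignment("g", {"a": ""})


class TestAlignmentFilters:
    def test_passes_with_informative_sites_and_codon_length(self):
        aln = CdsAlignment("g", {
            "a": "AAA" * 100, "b": "AAA" * 100,
            "c": "TAA" + "AAA" * 99, "d": "TAA" + "AAA" * 99,
        })
        ok, reason = alignment_passes_filters(aln)
        assert ok and reason == "pass"

    def test_fails_on_non_codon_length(self):
        aln = CdsAlignment("g", {
            "a": "A" * 301, "b": "A" * 301,
            "c": "T" + "A" * 300, "d": "T" + "A" * 300,
        })
        ok, reason = alignment_passes_filters(aln)
        assert not ok and reason == "length_not_multiple_of_3"

    def test_fails_without_informative_sites(self):
        aln = CdsAlignment("g", {"a": "A" * 300, "b": "A" * 300,
                                 "c": "A" * 300, "d": "G" + "A" * 299})
        ok, reason = alignment_passes_filters(aln)
        assert not ok and reason == "no_parsimony_informative_sites"


class TestGeneModelIO:
    def test_bed_and_gff3_agree(self, tmp_path):
        bed = tmp_path / "g.bed"
        bed.write_text("chr1\t100\t400\tgeneA\t0\t+\n")
        gff = tmp_path / "g.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t101\t400\t.\t+\t.\tID=geneA\n"
            "chr1\tsrc\tCDS\t101\t400\t.\t+\t0\tParent=geneA\n"
        )
        (from_bed,) = read_gene_models(bed)
        (from_gff,) = read_gene_models(gff)
        assert (from_bed.chrom, from_bed.start, from_bed.end) == \
            (from_gff.chrom, from_gff.start, from_gff.end) == \
            ("chr1", 101, 400)

    def test_unknown_extension_rejected(self, tmp_path):
        p = tmp_path / "g.txt"
        p.write_text("x")
        with pytest.raises(ValueError):
            read_gene_models(p)
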