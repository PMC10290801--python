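"""Gene-table I/O, backbone classification and assembly statistics."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from pksmine import genome
from pksmine.genome import (
    GeneModel,
    assembly_stats,
    classify_backbone,
    gc_content,
    matches_required,
    n50,
    read_gene_table,
    write_gene_table,
)

FULL = ("KS", "AT", "DH", "MT", "ER", "KR", "ACP")


def _toy_genes():
    return [
        GeneModel("g1", "scf_1", 100, 1500, "+", "PKS", FULL, cluster_id="c1"),
        GeneModel("g2", "scf_1", 2000, 2900, "-", "P450", ("P450",), cluster_id="c1"),
        GeneModel("g3", "scf_2", 50, 400, "+", "hypothetical", ()),
    ]


class TestGeneTableIO:
    def test_tsv_roundtrip(self, tmp_path):
        path = tmp_path / "genes.tsv"
        write_gene_table(_toy_genes(), path)
        back = read_gene_table(path)
        assert back == _toy_genes()

    def test_gff3_roundtrip(self, tmp_path):
        path = tmp_path / "genes.gff3"
        write_gene_table(_toy_genes(), path)
        back = read_gene_table(path)
        assert back == _toy_genes()

    def test_sorted_by_scaffold_and_start(self, tmp_path):
        path = tmp_path / "genes.tsv"
        write_gene_table(list(reversed(_toy_genes())), path)
        back = read_gene_table(path)
        assert [g.gene_id for g in back] == ["g1", "g2", "g3"]

    def test_semicolon_domains_parse(self, tmp_path):
        path = tmp_path / "genes.tsv"
        path.write_text(
            "gene_id\tscaffold\tstart\tend\tstrand\tproduct\tdomains\n"
            "g1\ts\t1\t10\t+\tx\tKS;AT;ACP\n"
        )
        (gene,) = read_gene_table(path)
        assert gene.architecture == ("KS", "AT", "ACP")

    def test_end_before_start_rejected(self, tmp_path):
        path = tmp_path / "genes.tsv"
        path.write_text(
            "gene_id\tscaffold\tstart\tend\tstrand\tproduct\tdomains\n"
            "g1\ts\t100\t10\t+\tx\t\n"
        )
        with pytest.raises(ValueError, match="end"):
            read_gene_table(path)

    def test_duplicate_gene_id_rejected(self, tmp_path):
        path = tmp_path / "genes.tsv"
        path.write_text(
            "gene_id\tscaffold\tstart\tend\tstrand\tproduct\tdomains\n"
            "g1\ts\t1\t10\t+\tx\t\ng1\ts\t20\t30\t+\tx\t\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_gene_table(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "genes.tsv"
        path.write_text("gene_id\tscaffold\tstart\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_gene_table(path)

    def test_unknown_domain_maps_to_unk_with_warning(self):
        with pytest.warns(UserWarning, match="UNK"):
            arch = genome.parse_architecture("KS;AT;FancyNewDomain")
        assert arch == ("KS", "AT", "UNK")


class TestBackboneClassification:
    @pytest.mark.parametrize(
        "arch,clazz,reduction",
        [
            (FULL, "PKS", "HR"),
            (("KS", "AT", "KR", "ACP"), "PKS", "PR"),
            (("KS", "AT", "ACP"), "PKS", "NR"),
            (("C", "A", "PCP"), "NRPS", "NA"),
            (("KS", "AT", "ACP", "C", "A", "PCP"), "PKS_NRPS_hybrid", "NA"),
            (("A",), "NRPS_like", "NA"),
            (("CHS_N", "CHS_C"), "type3_PKS", "NA"),
            (("TPS",), "TPS", "NA"),
            ((), "none", "NA"),
            (("P450", "MFS"), "none", "NA"),
        ],
    )
    def test_rule_table(self, arch, clazz, reduction):
        result = classify_backbone(arch)
        assert (result.clazz, result.reduction) == (clazz, reduction)

    @given(
        st.lists(st.sampled_from(sorted(genome.DOMAIN_CODES)), max_size=8)
    )
    @settings(derandomize=True, max_examples=150)
    def test_total_function(self, arch):
        result = classify_backbone(tuple(arch))
        assert result.clazz in {
            "PKS", "type3_PKS", "NRPS", "NRPS_like", "PKS_NRPS_hybrid", "TPS", "none"
        }
        assert (result.reduction == "NA") == (result.clazz != "PKS")

    def test_matches_required_is_set_containment(self):
        assert matches_required(FULL, set(FULL))
        assert not matches_required(("KS", "AT", "KR", "ACP"), set(FULL))
        # order-insensitive
        assert matches_required(tuple(reversed(FULL)), set(FULL))


class TestGCContent:
    def test_simple_values(self):
        assert gc_content(["ATGC"]) == 0.5
        assert gc_content(["GGCC"]) == 1.0

    def test_case_and_concatenation_invariance(self):
        assert gc_content(["atGcGG", "ttAA"]) == gc_content(["TTAA", "ATGCGG"])

    def test_ambiguity_codes_excluded(self):
        assert gc_content(["ATGCNNNN"]) == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gc_content(["NNN"])

    def test_fasta_path(self, tmp_path):
        path = tmp_path / "toy.fa"
        path.write_text(">a\nATGC\n>b\nGGGG\n")
        assert gc_content(path) == pytest.approx(6 / 8)


def _partitions(n, largest=None):
    """All integer partitions of n, largest part first."""
    largest = largest or n
    if n == 0:
        yield ()
        return
    for first in range(min(n, largest), 0, -1):
        for rest in _partitions(n - first, first):
            yield (first,) + rest


def _n50_oracle(lengths):
    total = sum(lengths)
    return max(L for L in lengths if 2 * sum(x for x in lengths if x >= L) >= total)


class TestN50:
    def test_worked_example(self):
        # total 20; cumulative 6, 11 >= 10 at length 5
        assert n50([6, 5, 4, 3, 2]) == 5

    def test_single_contig(self):
        assert n50([10]) == 10

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            n50([])

    def test_matches_exhaustive_oracle_on_all_small_partitions(self):
        for n in range(1, 16):
            for part in _partitions(n):
                assert n50(list(part)) == _n50_oracle(part), part


def test_assembly_stats(tmp_path):
    path = tmp_path / "asm.fa"
    path.write_text(">a\nATGCGC\n>b\nAT\n")
    stats = assembly_stats(path)
    assert stats["n_scaffolds"] == 2
    assert stats["total_bp"] == 8
    assert stats["gc"] == pytest.approx(4 / 8)
    assert stats["n50"] == 6
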