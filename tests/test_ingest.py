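"""Tests for evidence-table parsing, threshold filters and set assembly."""

import logging

import pytest
from hypothesis import given, settings, strategies as st

from comorbnet.errors import ComorbnetError, FormatError, RowError
from comorbnet.ingest import (
    assemble_disease_gene_set,
    de_genes_min_support,
    eqtl_regulated_genes,
    filter_coding_variants,
    filter_eqtl_fdr,
    parse_eqtl_table,
    parse_gwas_table,
    select_hpo_genes,
    text_mined_genes,
)
from comorbnet.types import (
    CuratedGeneList,
    EqtlLink,
    EvidenceChannel,
    ExpressionReport,
    HpoAnnotation,
    IngestConfig,
    VariantAssociation,
)

TRAITS = {"asthma": "asthma", "eosinophils": "asthma", "hypertension": "hypertension"}


def _write(path, text):
    path.write_text(text)
    return path


class TestParseGwas:
    HEADER = "snp_id\ttrait\tp_value\tconsequence\tmapped_gene\n"

    def test_all_rows_mapped(self, tmp_path):
        f = _write(
            tmp_path / "g.tsv",
            self.HEADER
            + "rs1\tasthma\t1e-6\tmissense_variant\tGENE1\n"
            + "rs2\teosinophils\t1e-7\tintron_variant\t\n"
            + "rs3\thypertension\t1e-8\tsynonymous_variant\tGENE2\n",
        )
        recs = parse_gwas_table(f, TRAITS)
        assert len(recs) == 3
        assert recs[0].trait == "asthma" and recs[1].trait == "asthma"
        assert recs[1].mapped_gene is None

    def test_unmapped_trait_dropped_and_logged(self, tmp_path, caplog):
        f = _write(
            tmp_path / "g.tsv",
            self.HEADER
            + "rs1\tasthma\t1e-6\tmissense_variant\tG1\n"
            + "rs2\theight\t1e-6\tmissense_variant\tG2\n"
            + "rs3\tasthma\t1e-6\tmissense_variant\tG3\n",
        )
        with caplog.at_level(logging.INFO, logger="comorbnet.ingest"):
            recs = parse_gwas_table(f, TRAITS)
        assert len(recs) == 2
        assert "dropped 1" in caplog.text

    def test_header_only_file(self, tmp_path):
        f = _write(tmp_path / "g.tsv", self.HEADER)
        assert parse_gwas_table(f, TRAITS) == []

    def test_missing_column_named_in_error(self, tmp_path):
        f = _write(tmp_path / "g.tsv", "snp_id\ttrait\tconsequence\nrs1\tasthma\tx\n")
        with pytest.raises(FormatError, match="p_value"):
            parse_gwas_table(f, TRAITS)

    def test_unparseable_p_value_reports_row(self, tmp_path):
        f = _write(
            tmp_path / "g.tsv",
            self.HEADER + "rs1\tasthma\toops\tmissense_variant\tG1\n",
        )
        with pytest.raises(RowError, match="row 1"):
            parse_gwas_table(f, TRAITS)


def _var(snp, p, cons, gene=None):
    return VariantAssociation(
        snp_id=snp, trait="asthma", p_value=p, consequence=cons, mapped_gene=gene
    )


class TestCodingFilter:
    CFG = IngestConfig()

    def test_coding_below_threshold_kept(self):
        assert filter_coding_variants([_var("rs1", 1e-6, "missense_variant")], self.CFG)

    def test_noncoding_dropped_despite_tiny_p(self):
        assert not filter_coding_variants(
            [_var("rs1", 1e-9, "intergenic_variant")], self.CFG
        )

    def test_p_exactly_at_threshold_dropped(self):
        assert not filter_coding_variants(
            [_var("rs1", 1e-5, "missense_variant")], self.CFG
        )

    def test_idempotent_and_order_preserving(self):
        variants = [
            _var("rs1", 1e-6, "missense_variant"),
            _var("rs2", 1e-9, "intron_variant"),
            _var("rs3", 2e-6, "synonymous_variant"),
        ]
        once = filter_coding_variants(variants, self.CFG)
        assert filter_coding_variants(once, self.CFG) == once
        assert [v.snp_id for v in once] == ["rs1", "rs3"]


class TestEqtl:
    HEADER = "snp_id\tgene\ttissue\tkind\tfdr\n"

    def test_parse_kinds_preserved(self, tmp_path):
        f = _write(
            tmp_path / "e.tsv",
            self.HEADER
            + "rs1\tG1\tblood\tcis\t0.01\n"
            + "rs2\tG2\tblood\tcis\t0.02\n"
            + "rs3\tG3\tblood\ttrans\t0.03\n",
        )
        links = parse_eqtl_table(f, "study1")
        assert [l.kind for l in links] == ["cis", "cis", "trans"]
        assert all(l.study == "study1" for l in links)

    def test_out_of_range_fdr_rejected(self, tmp_path):
        f = _write(tmp_path / "e.tsv", self.HEADER + "rs1\tG1\tblood\tcis\t1.5\n")
        with pytest.raises(RowError):
            parse_eqtl_table(f, "s")

    def test_bad_kind_rejected(self, tmp_path):
        f = _write(tmp_path / "e.tsv", self.HEADER + "rs1\tG1\tblood\tboth\t0.1\n")
        with pytest.raises(RowError):
            parse_eqtl_table(f, "s")

    def test_duplicate_key_named(self, tmp_path):
        f = _write(
            tmp_path / "e.tsv",
            self.HEADER
            + "rs1\tG1\tblood\tcis\t0.01\n"
            + "rs1\tG1\tblood\tcis\t0.02\n",
        )
        with pytest.raises(FormatError, match="rs1"):
            parse_eqtl_table(f, "s")

    def test_fdr_threshold_inclusive(self):
        cfg = IngestConfig()

        def link(fdr):
            return EqtlLink(
                snp_id="rs1", gene="G1", study="s", tissue="t", kind="cis", fdr=fdr
            )

        kept = filter_eqtl_fdr([link(0.049), link(0.05), link(0.051)], cfg)
        assert [l.fdr for l in kept] == [0.049, 0.05]

    def test_empty_input(self):
        assert filter_eqtl_fdr([], IngestConfig()) == []


class TestEqtlRegulatedGenes:
    def _link(self, snp, gene, study="s1"):
        return EqtlLink(
            snp_id=snp, gene=gene, study=study, tissue="t", kind="trans", fdr=0.01
        )

    def test_basic_overlap(self):
        gwas = [_var("rs1", 1e-6, "intron_variant")]
        links = [self._link("rs1", "G1"), self._link("rs2", "G2")]
        assert eqtl_regulated_genes(gwas, links) == {"G1": {("rs1", "s1")}}

    def test_trans_fanout_preserved(self):
        gwas = [_var("rs1", 1e-6, "intron_variant")]
        links = [self._link("rs1", g) for g in ("G1", "G2", "G3")]
        out = eqtl_regulated_genes(gwas, links)
        assert set(out) == {"G1", "G2", "G3"}

    def test_disjoint_sets_empty(self):
        gwas = [_var("rs9", 1e-6, "intron_variant")]
        assert eqtl_regulated_genes(gwas, [self._link("rs1", "G1")]) == {}

    def test_no_consequence_filter_applies(self):
        # even a coding-filter-failing variant participates in eQTL mapping
        gwas = [_var("rs1", 5e-4, "intergenic_variant")]
        links = [self._link("rs1", "G1")]
        assert "G1" in eqtl_regulated_genes(gwas, links)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_agrees_with_double_loop_oracle(self, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        snps = [f"rs{i}" for i in range(rng.integers(1, 12))]
        genes = [f"G{i}" for i in range(rng.integers(1, 12))]
        gwas = [
            _var(s, 1e-6, "intron_variant")
            for s in snps
            if rng.random() < 0.5
        ]
        links = [
            self._link(s, g)
            for s in snps
            for g in genes
            if rng.random() < 0.3
        ]
        expected: dict = {}
        for v in gwas:
            for l in links:
                if l.snp_id == v.snp_id:
                    expected.setdefault(l.gene, set()).add((l.snp_id, l.study))
        assert eqtl_regulated_genes(gwas, links) == expected


class TestHpo:
    CFG = IngestConfig(
        hpo_include_terms=frozenset({"HP:0000822"}),
        hpo_exclude_terms=frozenset({"HP:0007906"}),
    )

    def test_frequent_included_term_kept(self):
        ann = [HpoAnnotation(gene="G1", term_id="HP:0000822", frequency_label="frequent")]
        assert select_hpo_genes(ann, self.CFG) == {"G1"}

    def test_excluded_term_only_dropped(self):
        ann = [HpoAnnotation(gene="G1", term_id="HP:0007906", frequency_label="frequent")]
        assert select_hpo_genes(ann, self.CFG) == set()

    def test_exclusion_is_term_level_not_gene_level(self):
        ann = [
            HpoAnnotation(gene="G1", term_id="HP:0007906", frequency_label="frequent"),
            HpoAnnotation(gene="G1", term_id="HP:0000822", frequency_label="frequent"),
        ]
        assert select_hpo_genes(ann, self.CFG) == {"G1"}

    def test_occasional_label_dropped(self):
        ann = [HpoAnnotation(gene="G1", term_id="HP:0000822", frequency_label="occasional")]
        assert select_hpo_genes(ann, self.CFG) == set()

    def test_bad_prefix_rejected(self):
        with pytest.raises(RowError):
            HpoAnnotation(gene="G1", term_id="GO:0000822", frequency_label="frequent")


class TestDiffExpr:
    CFG = IngestConfig()

    def _rep(self, gene, source, trusted=False):
        return ExpressionReport(
            gene=gene, disease="asthma", direction="up", source=source, trusted=trusted
        )

    def test_single_trusted_signature_suffices(self):
        assert de_genes_min_support([self._rep("G1", "big_study", True)], self.CFG) == {"G1"}

    def test_same_source_twice_not_enough(self):
        reps = [self._rep("G1", "mine"), self._rep("G1", "mine")]
        assert de_genes_min_support(reps, self.CFG) == set()

    def test_two_distinct_untrusted_sources_suffice(self):
        reps = [self._rep("G1", "mine"), self._rep("G1", "curated")]
        assert de_genes_min_support(reps, self.CFG) == {"G1"}


class TestTextMining:
    CFG = IngestConfig()

    def test_support_threshold(self):
        lst = CuratedGeneList(
            disease="asthma",
            channel=EvidenceChannel.TEXT_MINING,
            entries={"G1": 2, "G2": 1, "G3": 100},
        )
        assert text_mined_genes(lst, self.CFG) == {"G1", "G3"}

    def test_empty_list(self):
        lst = CuratedGeneList(disease="a", channel=EvidenceChannel.TEXT_MINING)
        assert text_mined_genes(lst, self.CFG) == set()

    def test_wrong_channel_rejected(self):
        lst = CuratedGeneList(disease="a", channel=EvidenceChannel.MONOGENIC)
        with pytest.raises(ComorbnetError):
            text_mined_genes(lst, IngestConfig())


class TestAssemble:
    def test_channel_union_and_counts(self):
        dgs = assemble_disease_gene_set(
            "asthma",
            {
                EvidenceChannel.TEXT_MINING: {"G1", "G2"},
                EvidenceChannel.EQTL: {"G1": {"rs1@s1"}},
                EvidenceChannel.MONOGENIC: {"G3"},
            },
        )
        assert dgs.genes == {
            "G1": {EvidenceChannel.TEXT_MINING, EvidenceChannel.EQTL},
            "G2": {EvidenceChannel.TEXT_MINING},
            "G3": {EvidenceChannel.MONOGENIC},
        }
        # conservation: sum of per-gene channel-set sizes = sum of channel sizes
        assert sum(len(chs) for chs in dgs.genes.values()) == 4

    def test_case_normalization_and_alias(self):
        dgs = assemble_disease_gene_set(
            "asthma",
            {EvidenceChannel.TEXT_MINING: {"tp53", "p53_syn"}},
            aliases={"p53_syn": "TP53"},
        )
        assert set(dgs.genes) == {"TP53"}

    def test_mixed_namespace_rejected(self):
        with pytest.raises(ComorbnetError, match="namespace"):
            assemble_disease_gene_set(
                "asthma", {EvidenceChannel.TEXT_MINING: {"TP53", "7157"}}
            )

    def test_engineered_overlap_tally(self):
        # six channels with engineered overlaps over ten genes
        genes = [f"G{i}" for i in range(10)]
        channel_sets = {
            EvidenceChannel.MONOGENIC: set(genes[:3]),
            EvidenceChannel.CODING_GWAS: set(genes[2:5]),
            EvidenceChannel.EQTL: set(genes[4:8]),
            EvidenceChannel.DIFF_EXPR: set(genes[0:1]) | set(genes[9:]),
            EvidenceChannel.TEXT_MINING: set(genes),
            EvidenceChannel.DRUG_TARGET: set(genes[8:]),
        }
        dgs = assemble_disease_gene_set("asthma", channel_sets)
        assert len(dgs) == 10
        tally = {g: sum(g in s for s in channel_sets.values()) for g in genes}
        assert {g: len(chs) for g, chs in dgs.genes.items()} == tally


class TestConfigValidation:
    def test_overlapping_term_sets_rejected(self):
        with pytest.raises(ComorbnetError):
            IngestConfig(
                hpo_include_terms=frozenset({"HP:1"}),
                hpo_exclude_terms=frozenset({"HP:1"}),
            )

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ComorbnetError):
            IngestConfig(gwas_p_max=0.0)
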