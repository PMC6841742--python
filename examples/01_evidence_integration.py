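"""Assemble an evidence-labeled gene set for one disease from small tables.

Builds a handful of in-memory evidence records, applies the channel filters
(suggestive-GWAS p < 1e-5 with coding consequences, eQTL FDR <= 0.05,
'frequent' phenotype annotations, two-source expression support, two-study
text mining) and unions the surviving genes into one DiseaseGeneSet.
"""

from comorbnet import (
    EvidenceChannel,
    IngestConfig,
    assemble_disease_gene_set,
    de_genes_min_support,
    eqtl_regulated_genes,
    filter_coding_variants,
    filter_eqtl_fdr,
    select_hpo_genes,
    text_mined_genes,
)
from comorbnet.types import (
    CuratedGeneList,
    EqtlLink,
    ExpressionReport,
    HpoAnnotation,
    VariantAssociation,
)

cfg = IngestConfig(hpo_include_terms=frozenset({"HP:0000822"}))

gwas = [
    VariantAssociation("rs101", "hypertension", 2e-9, "missense_variant", "AGT"),
    VariantAssociation("rs102", "hypertension", 1e-5, "missense_variant", "DROP1"),
    VariantAssociation("rs103", "hypertension", 3e-8, "intron_variant", None),
]
coding = filter_coding_variants(gwas, cfg)
print(f"coding GWAS: kept {len(coding)}/3 variants "
      "(rs102 sits exactly at p = 1e-5, the threshold is strict)")

links = [
    EqtlLink("rs103", "NPPA", "studyX", "blood", "trans", 0.01),
    EqtlLink("rs103", "NPPB", "studyX", "blood", "trans", 0.04),
    EqtlLink("rs103", "CLCN6", "studyX", "blood", "cis", 0.2),
]
regulated = eqtl_regulated_genes(gwas, filter_eqtl_fdr(links, cfg))
print(f"eQTL channel: rs103 (non-coding, still a GWAS hit) regulates "
      f"{sorted(regulated)} after the FDR filter")

hpo = select_hpo_genes(
    [HpoAnnotation("WNK1", "HP:0000822", "frequent"),
     HpoAnnotation("CYP11B1", "HP:0000822", "occasional")],
    cfg,
)
de = de_genes_min_support(
    [ExpressionReport("FOS", "hypertension", "up", "signature", True),
     ExpressionReport("ONLY1", "hypertension", "up", "mining_a", False)],
    cfg,
)
text = text_mined_genes(
    CuratedGeneList("hypertension", EvidenceChannel.TEXT_MINING,
                    {"ACE": 40, "RARE": 1}),
    cfg,
)

dgs = assemble_disease_gene_set(
    "hypertension",
    {
        EvidenceChannel.CODING_GWAS: {v.mapped_gene for v in coding},
        EvidenceChannel.EQTL: {g: {f"{s}@{st}" for s, st in prov}
                               for g, prov in regulated.items()},
        EvidenceChannel.MONOGENIC: hpo,
        EvidenceChannel.DIFF_EXPR: de,
        EvidenceChannel.TEXT_MINING: text,
    },
)
print(f"\nassembled {len(dgs)} genes for hypertension:")
for gene in sorted(dgs.genes):
    print(f"  {gene:7s} <- {', '.join(sorted(c.value for c in dgs.genes[gene]))}")
print("each gene carries exactly the evidence channels that contributed it")
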