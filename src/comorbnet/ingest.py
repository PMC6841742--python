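"""Parsing and filtering of the six evidence-channel input tables.

All inputs are UTF-8 TSV files with a mandatory header row; lines starting
with '#' are ignored. Gene identifiers are normalized to one declared
namespace per run (HGNC-style symbols by default, upper-cased; or purely
numeric stable IDs) and an optional alias table maps synonyms onto canonical
identifiers. Mixing namespaces raises rather than silently merging.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

from .errors import ComorbnetError, FormatError, RowError
from .types import (
    CuratedGeneList,
    DiseaseGeneSet,
    EqtlLink,
    EvidenceChannel,
    ExpressionReport,
    HpoAnnotation,
    IngestConfig,
    VariantAssociation,
)

logger = logging.getLogger(__name__)

__all__ = [
    "parse_gwas_table",
    "filter_coding_variants",
    "parse_eqtl_table",
    "filter_eqtl_fdr",
    "eqtl_regulated_genes",
    "parse_hpo_table",
    "select_hpo_genes",
    "parse_expression_table",
    "de_genes_min_support",
    "parse_curated_list",
    "text_mined_genes",
    "curated_genes",
    "parse_alias_table",
    "assemble_disease_gene_set",
    "write_association_table",
]


def _read_tsv(path, required: Iterable[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    return df


def parse_gwas_table(
    path, trait_map: Mapping[str, str]
) -> list[VariantAssociation]:
    """Read a GWAS-catalog-style variant table and map traits to diseases.

    Rows whose trait is absent from ``trait_map`` are dropped and counted in
    the log. The ``trait`` field of the returned records holds the mapped
    disease label.
    """
    df = _read_tsv(path, ("snp_id", "trait", "p_value", "consequence"))
    has_gene = "mapped_gene" in df.columns
    records: list[VariantAssociation] = []
    dropped = 0
    for i, row in enumerate(df.itertuples(index=False), start=1):
        disease = trait_map.get(row.trait)
        if disease is None:
            dropped += 1
            continue
        try:
            p = float(row.p_value)
        except ValueError:
            raise RowError(f"{path}: row {i}: unparseable p_value {row.p_value!r}")
        gene = row.mapped_gene if has_gene and row.mapped_gene else None
        records.append(
            VariantAssociation(
                snp_id=row.snp_id, trait=disease, p_value=p,
                consequence=row.consequence, mapped_gene=gene,
            )
        )
    if dropped:
        logger.info("%s: dropped %d row(s) with unmapped traits", path, dropped)
    return records


def filter_coding_variants(
    variants: list[VariantAssociation], cfg: IngestConfig
) -> list[VariantAssociation]:
    """Keep variants below the GWAS p threshold (strict) with a coding-class
    consequence; input order is preserved."""
    if not cfg.allowed_consequences:
        raise ComorbnetError("allowed_consequences must be non-empty")
    return [
        v
        for v in variants
        if v.p_value < cfg.gwas_p_max and v.consequence in cfg.allowed_consequences
    ]


def parse_eqtl_table(path, study: str) -> list[EqtlLink]:
    """Read one eQTL study's SNP-gene link table; links are labeled ``study``."""
    df = _read_tsv(path, ("snp_id", "gene", "tissue", "kind", "fdr"))
    links: list[EqtlLink] = []
    seen: set[tuple[str, str, str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            fdr = float(row.fdr)
        except ValueError:
            raise RowError(f"{path}: row {i}: unparseable fdr {row.fdr!r}")
        link = EqtlLink(
            snp_id=row.snp_id, gene=row.gene, study=study,
            tissue=row.tissue, kind=row.kind, fdr=fdr,
        )
        if link.key in seen:
            raise FormatError(f"{path}: duplicate SNP-gene link {link.key}")
        seen.add(link.key)
        links.append(link)
    return links


def filter_eqtl_fdr(links: list[EqtlLink], cfg: IngestConfig) -> list[EqtlLink]:
    """Keep links passing the FDR threshold (inclusive <=)."""
    return [l for l in links if l.fdr <= cfg.eqtl_fdr_max]


def eqtl_regulated_genes(
    gwas: list[VariantAssociation], links: list[EqtlLink]
) -> dict[str, set[tuple[str, str]]]:
    """Genes regulated by at least one disease-associated GWAS SNP.

    All GWAS variants of the disease participate, not only coding ones; the
    returned mapping carries every supporting (snp_id, study) pair, so trans
    fan-out is preserved.
    """
    snp_set = {v.snp_id for v in gwas}
    out: dict[str, set[tuple[str, str]]] = {}
    for link in links:
        if link.snp_id in snp_set:
            out.setdefault(link.gene, set()).add((link.snp_id, link.study))
    return out


def parse_hpo_table(path) -> list[HpoAnnotation]:
    df = _read_tsv(path, ("gene", "term_id", "frequency_label"))
    return [
        HpoAnnotation(gene=r.gene, term_id=r.term_id, frequency_label=r.frequency_label)
        for r in df.itertuples(index=False)
    ]


def select_hpo_genes(annotations: list[HpoAnnotation], cfg: IngestConfig) -> set[str]:
    """Genes with a qualifying phenotype annotation.

    A gene qualifies through any single annotation whose term is in the
    include set (and not in the exclude set) and whose frequency label is
    allowed. Exclusion removes *annotations*, not genes: a gene annotated to
    both an included and an excluded term stays in through the included one.
    """
    if not cfg.hpo_include_terms:
        raise ComorbnetError("hpo_include_terms must be non-empty")
    return {
        a.gene
        for a in annotations
        if a.term_id in cfg.hpo_include_terms
        and a.term_id not in cfg.hpo_exclude_terms
        and a.frequency_label in cfg.hpo_frequency_labels
    }


def parse_expression_table(path) -> list[ExpressionReport]:
    df = _read_tsv(path, ("gene", "disease", "direction", "source", "trusted"))
    reports = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        val = row.trusted.strip().lower()
        if val not in ("true", "false", "1", "0"):
            raise RowError(f"{path}: row {i}: unparseable trusted flag {row.trusted!r}")
        reports.append(
            ExpressionReport(
                gene=row.gene, disease=row.disease, direction=row.direction,
                source=row.source, trusted=val in ("true", "1"),
            )
        )
    return reports


def de_genes_min_support(
    reports: list[ExpressionReport], cfg: IngestConfig
) -> set[str]:
    """Differentially expressed genes with sufficient support.

    A gene qualifies if it appears in any trusted signature, or in reports
    from at least ``de_min_sources`` *distinct* untrusted sources (row count
    does not matter).
    """
    trusted: set[str] = set()
    sources: dict[str, set[str]] = {}
    for r in reports:
        if r.trusted:
            trusted.add(r.gene)
        else:
            sources.setdefault(r.gene, set()).add(r.source)
    return trusted | {
        g for g, srcs in sources.items() if len(srcs) >= cfg.de_min_sources
    }


def parse_curated_list(path, disease: str, channel: EvidenceChannel) -> CuratedGeneList:
    """Read a curated/text-mined gene list (columns disease, gene, support_count),
    keeping only rows of ``disease``."""
    df = _read_tsv(path, ("disease", "gene", "support_count"))
    entries: dict[str, int] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.disease != disease:
            continue
        try:
            count = int(row.support_count)
        except ValueError:
            raise RowError(
                f"{path}: row {i}: unparseable support_count {row.support_count!r}"
            )
        entries[row.gene] = max(count, entries.get(row.gene, 0))
    return CuratedGeneList(disease=disease, channel=channel, entries=entries)


def text_mined_genes(lst: CuratedGeneList, cfg: IngestConfig) -> set[str]:
    """Text-mined genes supported by at least ``text_min_studies`` studies."""
    if lst.channel is not EvidenceChannel.TEXT_MINING:
        raise ComorbnetError("text_mined_genes expects a text_mining list")
    return {g for g, n in lst.entries.items() if n >= cfg.text_min_studies}


def curated_genes(lst: CuratedGeneList, min_support: int = 1) -> set[str]:
    """Genes of a curated list with support >= ``min_support`` (monogenic
    syndrome lists use 1)."""
    return {g for g, n in lst.entries.items() if n >= min_support}


def parse_alias_table(path) -> dict[str, str]:
    df = _read_tsv(path, ("alias", "canonical"))
    return {r.alias: r.canonical for r in df.itertuples(index=False)}


def _normalize_gene(gene: str, namespace: str, aliases: Mapping[str, str]) -> str:
    g = gene.strip()
    g = aliases.get(g, aliases.get(g.upper(), g))
    if namespace == "symbol":
        g = g.upper()
        if g.isdigit():
            raise ComorbnetError(
                f"gene {gene!r} looks like a numeric ID but the declared "
                "namespace is 'symbol' (mixed namespaces are refused)"
            )
    elif namespace == "entrez":
        if not g.isdigit():
            raise ComorbnetError(
                f"gene {gene!r} is not a numeric ID but the declared "
                "namespace is 'entrez' (mixed namespaces are refused)"
            )
    return g


ChannelInput = Union[set, Mapping[str, Iterable[str]]]


def assemble_disease_gene_set(
    disease: str,
    channel_sets: Mapping[EvidenceChannel, ChannelInput],
    namespace: str = "symbol",
    aliases: Optional[Mapping[str, str]] = None,
) -> DiseaseGeneSet:
    """Union the per-channel gene sets into one evidence-labeled set.

    Each channel may be a plain gene set or a mapping gene -> iterable of
    provenance detail strings. A gene's channel set is exactly the channels
    that contributed it.
    """
    aliases = dict(aliases or {})
    genes: dict[str, set[EvidenceChannel]] = {}
    provenance: dict[str, list[tuple[EvidenceChannel, str]]] = {}
    for channel in sorted(channel_sets, key=lambda c: c.value):
        payload = channel_sets[channel]
        if isinstance(payload, Mapping):
            items = [(g, sorted(str(d) for d in details)) for g, details in payload.items()]
        else:
            items = [(g, [""]) for g in payload]
        for raw_gene, details in sorted(items):
            gene = _normalize_gene(raw_gene, namespace, aliases)
            genes.setdefault(gene, set()).add(channel)
            prov = provenance.setdefault(gene, [])
            for detail in details:
                prov.append((channel, detail))
    return DiseaseGeneSet(disease=disease, genes=genes, provenance=provenance)


def write_association_table(dgs: DiseaseGeneSet, path) -> None:
    """Write the per-disease association table: gene, ';'-joined sorted
    channels, provenance as a JSON-in-cell string."""
    import json

    with open(path, "w") as fh:
        fh.write("gene\tchannels\tprovenance\n")
        for gene in sorted(dgs.genes):
            channels = ";".join(sorted(c.value for c in dgs.genes[gene]))
            prov = json.dumps(
                [[c.value, d] for c, d in sorted(dgs.provenance.get(gene, []))],
                sort_keys=True,
            )
            fh.write(f"{gene}\t{channels}\t{prov}\n")
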