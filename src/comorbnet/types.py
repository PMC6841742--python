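"""Domain types shared across the evidence-integration pipeline.

A *disease gene set* is the central container: for one disease it maps every
associated gene to the set of evidence channels that support the association
(monogenic syndromes, coding GWAS variants, eQTL regulation, differential
expression, text mining, drug targeting), plus free-form provenance detail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .errors import RowError, ConfigError


class EvidenceChannel(str, Enum):
    """Closed vocabulary of gene-disease evidence classes."""

    MONOGENIC = "monogenic"
    CODING_GWAS = "coding_gwas"
    EQTL = "eqtl"
    DIFF_EXPR = "diff_expr"
    TEXT_MINING = "text_mining"
    DRUG_TARGET = "drug_target"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: All channels, in a fixed report order.
CHANNELS: tuple[EvidenceChannel, ...] = tuple(EvidenceChannel)


@dataclass(frozen=True)
class VariantAssociation:
    """One variant-trait association, with the trait already mapped to a disease label."""

    snp_id: str
    trait: str
    p_value: float
    consequence: str
    mapped_gene: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise RowError("variant association with empty snp_id")
        if not (0.0 < self.p_value <= 1.0):
            raise RowError(
                f"variant {self.snp_id}: p_value {self.p_value!r} outside (0, 1]"
            )


@dataclass(frozen=True)
class EqtlLink:
    """One SNP-to-gene regulatory link reported by an eQTL study."""

    snp_id: str
    gene: str
    study: str
    tissue: str
    kind: str  # "cis" or "trans"
    fdr: float

    def __post_init__(self) -> None:
        if self.kind not in ("cis", "trans"):
            raise RowError(f"eQTL link {self.snp_id}->{self.gene}: kind {self.kind!r} "
                           "not in {'cis', 'trans'}")
        if not (0.0 <= self.fdr <= 1.0):
            raise RowError(f"eQTL link {self.snp_id}->{self.gene}: FDR {self.fdr!r} "
                           "outside [0, 1]")

    @property
    def key(self) -> tuple[str, str, str, str]:
        """Uniqueness key within one table."""
        return (self.snp_id, self.gene, self.study, self.tissue)


@dataclass(frozen=True)
class HpoAnnotation:
    """A gene-to-phenotype-term annotation with a clinical frequency label."""

    gene: str
    term_id: str
    frequency_label: str
    ontology_prefix: str = "HP:"

    def __post_init__(self) -> None:
        if not self.term_id.startswith(self.ontology_prefix):
            raise RowError(
                f"annotation for {self.gene}: term {self.term_id!r} does not match "
                f"ontology prefix {self.ontology_prefix!r}"
            )


@dataclass(frozen=True)
class ExpressionReport:
    """One differential-expression report for a gene in a disease.

    ``trusted`` marks signatures from a single large profiling study, which
    qualify a gene on their own; untrusted (text-mining collection) reports
    must agree across distinct sources.
    """

    gene: str
    disease: str
    direction: str  # up / down / unspecified
    source: str
    trusted: bool

    def __post_init__(self) -> None:
        if not self.source:
            raise RowError(f"expression report for {self.gene}: empty source")
        if self.direction not in ("up", "down", "unspecified"):
            raise RowError(
                f"expression report for {self.gene}: direction {self.direction!r}"
            )


@dataclass
class CuratedGeneList:
    """A curated or text-mined gene list with per-gene study-support counts."""

    disease: str
    channel: EvidenceChannel
    entries: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, count in self.entries.items():
            if count < 1:
                raise RowError(f"curated list entry {gene}: support_count {count} < 1")


@dataclass
class DiseaseGeneSet:
    """All genes associated with one disease, labeled by evidence channel."""

    disease: str
    genes: dict[str, set[EvidenceChannel]] = field(default_factory=dict)
    provenance: dict[str, list[tuple[EvidenceChannel, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, channels in self.genes.items():
            if not channels:
                raise RowError(f"gene {gene} has an empty evidence-channel set")

    def with_channel(self, channel: EvidenceChannel) -> set[str]:
        """Genes supported by ``channel``."""
        return {g for g, chs in self.genes.items() if channel in chs}

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass
class IngestConfig:
    """Scalar thresholds applied while assembling evidence channels.

    Defaults correspond to the standard curation rules: suggestive GWAS
    significance 1e-5 (strict ``<``), eQTL FDR 0.05 (inclusive ``<=``),
    phenotype annotations restricted to the "frequent" clinical label, and a
    two-independent-sources minimum for expression and text-mining evidence.
    """

    gwas_p_max: float = 1e-5
    eqtl_fdr_max: float = 0.05
    allowed_consequences: frozenset[str] = frozenset(
        {
            "splice_region_variant",
            "missense_variant",
            "synonymous_variant",
            "non_coding_transcript_exon_variant",
        }
    )
    hpo_include_terms: frozenset[str] = frozenset()
    hpo_exclude_terms: frozenset[str] = frozenset()
    hpo_frequency_labels: frozenset[str] = frozenset({"frequent"})
    de_min_sources: int = 2
    text_min_studies: int = 2
    namespace: str = "symbol"  # or "entrez"

    def __post_init__(self) -> None:
        if self.gwas_p_max <= 0 or self.eqtl_fdr_max <= 0:
            raise ConfigError("thresholds must be strictly positive")
        overlap = set(self.hpo_include_terms) & set(self.hpo_exclude_terms)
        if overlap:
            raise ConfigError(
                f"HPO include and exclude term sets overlap: {sorted(overlap)}"
            )
        if self.de_min_sources < 1 or self.text_min_studies < 1:
            raise ConfigError("minimum source counts must be >= 1")
        if self.namespace not in ("symbol", "entrez"):
            raise ConfigError(f"unknown gene namespace {self.namespace!r}")

    def replace(self, **kwargs) -> "IngestConfig":
        from dataclasses import replace

        return replace(self, **kwargs)
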