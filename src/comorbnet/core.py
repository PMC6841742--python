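"""Shared-gene tables, novelty flags and evidence-channel enrichment.

The intersection of two evidence-labeled disease gene sets forms the
shared-gene table; each row records the channels supporting the gene for
each disease and the combined evidence count. The enrichment background
("universe") defaults to all genes attested anywhere in the run's inputs and
is always carried explicitly, because co-association p-values depend
strongly on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import ComorbnetError
from .stats import FisherResult, fisher_one_sided
from .types import DiseaseGeneSet, EvidenceChannel

__all__ = [
    "SharedGeneRow",
    "SharedGeneTable",
    "NoveltyFlags",
    "shared_gene_table",
    "novelty_flags",
    "channel_enrichment",
    "write_shared_table",
]


@dataclass(frozen=True)
class SharedGeneRow:
    gene: str
    channels_a: frozenset[EvidenceChannel]
    channels_b: frozenset[EvidenceChannel]

    @property
    def evidence_count(self) -> int:
        return len(self.channels_a | self.channels_b)


@dataclass
class SharedGeneTable:
    disease_a: str
    disease_b: str
    rows: list[SharedGeneRow]
    universe: set[str]

    @property
    def genes(self) -> list[str]:
        return [r.gene for r in self.rows]

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class NoveltyFlags:
    """Per-shared-gene novelty: True when absent from every reference set."""

    novel: dict[str, bool]
    membership: dict[str, set[str]]  # reference name -> genes of the table it contains

    @property
    def n_novel(self) -> int:
        return sum(self.novel.values())


def shared_gene_table(
    a: DiseaseGeneSet, b: DiseaseGeneSet, universe: set[str]
) -> SharedGeneTable:
    """Rows for exactly the genes associated with both diseases.

    Sorted by (evidence count desc, gene asc); the universe is stored for
    downstream enrichment tests and must be non-empty.
    """
    if not universe:
        raise ComorbnetError("shared-gene table requires a non-empty universe")
    shared = sorted(set(a.genes) & set(b.genes))
    rows = [
        SharedGeneRow(
            gene=g,
            channels_a=frozenset(a.genes[g]),
            channels_b=frozenset(b.genes[g]),
        )
        for g in shared
    ]
    rows.sort(key=lambda r: (-r.evidence_count, r.gene))
    return SharedGeneTable(
        disease_a=a.disease, disease_b=b.disease, rows=rows, universe=set(universe)
    )


def novelty_flags(
    tbl: SharedGeneTable, references: Sequence[tuple[str, Iterable[str]]]
) -> NoveltyFlags:
    """Flag shared genes absent from every supplied reference gene set."""
    ref_sets = [(name, set(genes)) for name, genes in references]
    shared = set(tbl.genes)
    membership = {name: shared & genes for name, genes in ref_sets}
    novel = {
        g: all(g not in genes for _, genes in ref_sets) for g in sorted(shared)
    }
    return NoveltyFlags(novel=novel, membership=membership)


def channel_enrichment(
    tbl: SharedGeneTable,
    channel: EvidenceChannel,
    a: DiseaseGeneSet,
    b: DiseaseGeneSet,
    universe: set[str] | None = None,
) -> FisherResult:
    """One-sided Fisher test for co-occurrence of one evidence channel.

    Over the universe, the 2x2 table crosses "gene carries ``channel`` for
    disease A" with the same for disease B. A zero margin yields p = 1 with
    the degenerate flag set.
    """
    universe = set(universe) if universe is not None else set(tbl.universe)
    missing = (set(a.genes) | set(b.genes)) - universe
    if missing:
        raise ComorbnetError(
            f"universe must contain all genes of both disease sets; missing "
            f"{sorted(missing)[:5]}"
        )
    in_a = a.with_channel(channel) & universe
    in_b = b.with_channel(channel) & universe
    n11 = len(in_a & in_b)
    n10 = len(in_a - in_b)
    n01 = len(in_b - in_a)
    n00 = len(universe) - n11 - n10 - n01
    return fisher_one_sided(n11, n10, n01, n00)


def write_shared_table(
    tbl: SharedGeneTable, path, flags: NoveltyFlags | None = None
) -> None:
    """Export the shared-gene table as TSV (one row per shared gene)."""
    with open(path, "w") as fh:
        fh.write(
            f"gene\tchannels_{tbl.disease_a}\tchannels_{tbl.disease_b}"
            "\tevidence_count\tnovel\n"
        )
        for row in tbl.rows:
            ca = ";".join(sorted(c.value for c in row.channels_a))
            cb = ";".join(sorted(c.value for c in row.channels_b))
            novel = ""
            if flags is not None:
                novel = "yes" if flags.novel.get(row.gene, False) else "no"
            fh.write(f"{row.gene}\t{ca}\t{cb}\t{row.evidence_count}\t{novel}\n")
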