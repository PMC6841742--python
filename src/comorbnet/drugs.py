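"""Drug groups, action simplification and drug-target gene sets.

For each disease two drug groups are built: *beneficial* (indicated) and
*harmful* (contraindicated or reported to worsen the disease, pooled into one
polarity with the original flag kept in provenance). Drugs that appear both
indicated and contraindicated for the same disease — paradoxical reactions —
are removed from the harmful group only, since such reactions are rare.
Raw target action vocabularies are collapsed to three simplified effects:
positive (agonists, activators), negative (inhibitors, antagonists) and
other (modifiers), and only human targets are ever emitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Optional

import pandas as pd

from .errors import ComorbnetError, FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "TargetAction",
    "DrugRecord",
    "DrugGroup",
    "DrugGroups",
    "DEFAULT_ACTION_MAP",
    "HUMAN_ORGANISMS",
    "simplify_action",
    "parse_drug_tables",
    "build_drug_groups",
    "group_target_genes",
    "cross_disease_harm_overlap",
]

#: Organism labels counted as human (case-insensitive comparison).
HUMAN_ORGANISMS = frozenset({"human", "homo sapiens"})

#: Default raw-action to simplified-effect mapping; user-overridable.
DEFAULT_ACTION_MAP: dict[str, str] = {
    "agonist": "positive",
    "activator": "positive",
    "inducer": "positive",
    "potentiator": "positive",
    "partial agonist": "positive",
    "stimulator": "positive",
    "antagonist": "negative",
    "inhibitor": "negative",
    "blocker": "negative",
    "suppressor": "negative",
    "modifier": "other",
    "ligand": "other",
    "binder": "other",
    "unknown": "other",
}


@dataclass(frozen=True)
class TargetAction:
    gene: str
    action_raw: str
    human: bool

    def __post_init__(self) -> None:
        if not self.action_raw:
            raise ComorbnetError(f"target {self.gene}: empty raw action")


@dataclass
class DrugRecord:
    drug_id: str
    name: str
    targets: list[TargetAction] = field(default_factory=list)
    indicated: set[str] = field(default_factory=set)
    contraindicated: set[str] = field(default_factory=set)
    adverse_inducing: set[str] = field(default_factory=set)


@dataclass
class DrugGroup:
    disease: str
    polarity: str  # "beneficial" or "harmful"
    drugs: frozenset[str]


class DrugGroups(NamedTuple):
    """Result of group construction for one disease."""

    beneficial: DrugGroup
    harmful: DrugGroup
    paradoxical: tuple[str, ...]  # drugs removed from the harmful group


def simplify_action(
    action_raw: str,
    mapping_table: Optional[Mapping[str, str]] = None,
    unknown: str = "error",
) -> str:
    """Map a raw action term to positive / negative / other (case-insensitive).

    Unknown terms either raise (default) or map to ``other`` with a logged
    warning when ``unknown='other'``.
    """
    table = {k.lower(): v for k, v in (mapping_table or DEFAULT_ACTION_MAP).items()}
    effect = table.get(action_raw.strip().lower())
    if effect is None:
        if unknown == "other":
            logger.warning("unknown action term %r mapped to 'other'", action_raw)
            return "other"
        raise ComorbnetError(f"unknown drug action term {action_raw!r}")
    return effect


def _split_multi(cell: str) -> set[str]:
    return {part.strip() for part in cell.split(";") if part.strip()}


def parse_drug_tables(drug_path, target_path) -> list[DrugRecord]:
    """Read the drug table and its companion target table.

    Drug TSV columns: drug_id, name, indicated, contraindicated,
    adverse_inducing (';'-joined disease labels). Target TSV columns:
    drug_id, gene, action_raw, organism.
    """
    drugs_df = pd.read_csv(drug_path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    for col in ("drug_id", "name", "indicated", "contraindicated", "adverse_inducing"):
        if col not in drugs_df.columns:
            raise FormatError(f"{drug_path}: missing mandatory column {col!r}")
    targets_df = pd.read_csv(target_path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    for col in ("drug_id", "gene", "action_raw", "organism"):
        if col not in targets_df.columns:
            raise FormatError(f"{target_path}: missing mandatory column {col!r}")
    records: dict[str, DrugRecord] = {}
    for row in drugs_df.itertuples(index=False):
        if row.drug_id in records:
            raise FormatError(f"{drug_path}: duplicate drug_id {row.drug_id!r}")
        records[row.drug_id] = DrugRecord(
            drug_id=row.drug_id,
            name=row.name,
            indicated=_split_multi(row.indicated),
            contraindicated=_split_multi(row.contraindicated),
            adverse_inducing=_split_multi(row.adverse_inducing),
        )
    for row in targets_df.itertuples(index=False):
        rec = records.get(row.drug_id)
        if rec is None:
            raise FormatError(f"{target_path}: target row for unknown drug {row.drug_id!r}")
        rec.targets.append(
            TargetAction(
                gene=row.gene,
                action_raw=row.action_raw,
                human=row.organism.strip().lower() in HUMAN_ORGANISMS,
            )
        )
    return [records[d] for d in sorted(records)]


def build_drug_groups(drugs: list[DrugRecord], disease: str) -> DrugGroups:
    """Beneficial and harmful drug groups for one disease.

    harmful = contraindicated or adverse-inducing; drugs appearing in both the
    beneficial and harmful candidate sets (paradoxical reactions) are removed
    from the harmful group only and reported.
    """
    beneficial = {d.drug_id for d in drugs if disease in d.indicated}
    harmful_raw = {
        d.drug_id
        for d in drugs
        if disease in d.contraindicated or disease in d.adverse_inducing
    }
    paradoxical = tuple(sorted(beneficial & harmful_raw))
    harmful = harmful_raw - beneficial
    if paradoxical:
        logger.info(
            "%s: %d paradoxical drug(s) kept beneficial only: %s",
            disease, len(paradoxical), ", ".join(paradoxical),
        )
    return DrugGroups(
        beneficial=DrugGroup(disease=disease, polarity="beneficial", drugs=frozenset(beneficial)),
        harmful=DrugGroup(disease=disease, polarity="harmful", drugs=frozenset(harmful)),
        paradoxical=paradoxical,
    )


def group_target_genes(
    group: DrugGroup,
    drugs: list[DrugRecord],
    mapping_table: Optional[Mapping[str, str]] = None,
    unknown: str = "error",
) -> dict[str, set[tuple[str, str]]]:
    """Human target genes of a drug group with per-drug simplified effects.

    Returns gene -> set of (drug_id, simplified effect); non-human targets are
    never emitted.
    """
    by_id = {d.drug_id: d for d in drugs}
    missing = sorted(set(group.drugs) - set(by_id))
    if missing:
        raise ComorbnetError(f"group drugs absent from drug table: {', '.join(missing)}")
    out: dict[str, set[tuple[str, str]]] = {}
    for drug_id in sorted(group.drugs):
        for t in by_id[drug_id].targets:
            if not t.human:
                continue
            effect = simplify_action(t.action_raw, mapping_table, unknown=unknown)
            out.setdefault(t.gene, set()).add((drug_id, effect))
    return out


def cross_disease_harm_overlap(
    beneficial_a: DrugGroup, harmful_b: DrugGroup
) -> list[str]:
    """Drugs that treat one disease while harming the other (sorted)."""
    return sorted(beneficial_a.drugs & harmful_b.drugs)
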