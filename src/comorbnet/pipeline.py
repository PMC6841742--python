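"""Config-driven orchestration of the full comorbidity analysis.

Stage order: evidence ingest per disease -> drug group construction ->
shared-gene table and novelty -> functional network and overlapping module
detection -> module annotation -> drug-target overrepresentation and
cross-disease drug overlap tests -> evidence-channel enrichment and the
matched eQTL permutation test. Every filter logs an (in, kept, dropped)
triple; all randomness flows from the single mandatory seed; outputs are
plain text (TSV / GraphML / JSON) and byte-stable across reruns.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import yaml

from . import core, drugs, ingest, network, stats
from .errors import ComorbnetError, ConfigError
from .types import CHANNELS, DiseaseGeneSet, EvidenceChannel, IngestConfig

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ReportBundle", "validate_config", "run_pipeline", "parse_gmt"]

_MANDATORY_PATHS = (
    "gwas",
    "eqtl",
    "hpo",
    "curated_monogenic",
    "expression",
    "text_mining",
    "drugs",
    "drug_targets",
    "edges",
)
_OPTIONAL_PATHS = ("collections", "references", "aliases")
_THRESHOLD_DEFAULTS = {
    "gwas_p_max": 1.0e-5,
    "eqtl_fdr_max": 0.05,
    "de_min_sources": 2,
    "text_min_studies": 2,
    "min_clique": 10,
    "min_complex": 10,
    "alpha": 0.05,
    "n_perm": 10000,
}
_TOP_KEYS = {
    "diseases",
    "paths",
    "trait_map",
    "hpo_terms",
    "thresholds",
    "seed",
    "namespace",
}


@dataclass
class RunConfig:
    diseases: tuple[str, str]
    paths: dict
    trait_map: dict[str, str]
    hpo_terms: dict[str, dict[str, list[str]]]
    thresholds: dict
    seed: int
    namespace: str = "symbol"
    base_dir: Path = field(default_factory=Path)
    raw: dict = field(default_factory=dict, repr=False)

    def path(self, key: str):
        value = self.paths.get(key)
        if value is None:
            return None
        if isinstance(value, dict):
            return {k: self.base_dir / v for k, v in sorted(value.items())}
        return self.base_dir / value

    def ingest_config(self, disease: str) -> IngestConfig:
        terms = self.hpo_terms.get(disease, {})
        return IngestConfig(
            gwas_p_max=float(self.thresholds["gwas_p_max"]),
            eqtl_fdr_max=float(self.thresholds["eqtl_fdr_max"]),
            de_min_sources=int(self.thresholds["de_min_sources"]),
            text_min_studies=int(self.thresholds["text_min_studies"]),
            hpo_include_terms=frozenset(terms.get("include", [])),
            hpo_exclude_terms=frozenset(terms.get("exclude", [])),
            namespace=self.namespace,
        )

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def validate_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Unknown keys raise (no silent typo tolerance); defaults are filled for
    thresholds; every referenced input path must exist; the seed is
    mandatory so no run is silently nondeterministic.
    """
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a key-value mapping")
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    for key in ("diseases", "paths", "trait_map", "seed"):
        if key not in data:
            raise ConfigError(f"missing mandatory config key {key!r}")
    diseases = tuple(data["diseases"])
    if len(diseases) != 2:
        raise ConfigError("exactly two disease labels are required")
    paths = data["paths"]
    unknown_paths = set(paths) - set(_MANDATORY_PATHS) - set(_OPTIONAL_PATHS)
    if unknown_paths:
        raise ConfigError(f"unknown path key(s): {sorted(unknown_paths)}")
    missing = [k for k in _MANDATORY_PATHS if k not in paths]
    if missing:
        raise ConfigError(f"missing mandatory path(s): {missing}")
    thresholds = dict(_THRESHOLD_DEFAULTS)
    extra = set(data.get("thresholds", {})) - set(_THRESHOLD_DEFAULTS)
    if extra:
        raise ConfigError(f"unknown threshold key(s): {sorted(extra)}")
    thresholds.update(data.get("thresholds", {}))
    if thresholds["min_clique"] < 2:
        raise ConfigError("min_clique must be >= 2")
    if thresholds["min_complex"] < 1:
        raise ConfigError("min_complex must be >= 1")
    if thresholds["n_perm"] < 1:
        raise ConfigError("n_perm must be >= 1")
    base = path.parent
    cfg = RunConfig(
        diseases=diseases,
        paths=paths,
        trait_map=dict(data["trait_map"]),
        hpo_terms=data.get("hpo_terms", {}),
        thresholds=thresholds,
        seed=int(data["seed"]),
        namespace=data.get("namespace", "symbol"),
        base_dir=base,
        raw=data,
    )
    for key in _MANDATORY_PATHS:
        resolved = cfg.path(key)
        targets = resolved.values() if isinstance(resolved, dict) else [resolved]
        for p in targets:
            if not Path(p).exists():
                raise ConfigError(f"input path for {key!r} does not exist: {p}")
    for key in _OPTIONAL_PATHS:
        resolved = cfg.path(key)
        if resolved is not None and not Path(resolved).exists():
            raise ConfigError(f"input path for {key!r} does not exist: {resolved}")
    return cfg


def parse_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection (term, description, members...)."""
    collections: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            collections[parts[0]] = {g for g in parts[2:] if g}
    return collections


@dataclass
class ReportBundle:
    """All products of one pipeline run, with filter counts and provenance."""

    config_hash: str
    disease_sets: dict[str, DiseaseGeneSet]
    shared: core.SharedGeneTable
    novelty: Optional[core.NoveltyFlags]
    net: network.Network
    cover: network.Cover
    annotations: list[network.ModuleAnnotation]
    drug_groups: dict[tuple[str, str], drugs.DrugGroup]
    paradoxical: dict[str, tuple[str, ...]]
    cross_overlap: dict[str, list[str]]
    overlap_tests: dict[str, stats.FisherResult]
    drug_overrep: dict[tuple[str, str], list[stats.EnrichmentResult]]
    channel_tests: dict[EvidenceChannel, stats.FisherResult]
    permutation: stats.PermutationResult
    counts: dict
    status: str = "complete"


def _norm_set(raw: set[str], namespace: str, aliases: dict[str, str]) -> set[str]:
    return {ingest._normalize_gene(g, namespace, aliases) for g in raw}


def run_pipeline(cfg: RunConfig, out_dir) -> ReportBundle:
    """Execute the full analysis and write the report bundle to ``out_dir``.

    On a stage failure the partial outputs written so far are retained,
    summary.json is flagged incomplete, and the exception propagates.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {"config_hash": cfg.config_hash}
    log_lines: list[str] = [f"config_hash\t{cfg.config_hash}"]

    def note(stage: str, **kv) -> None:
        counts.setdefault(stage, {}).update(kv)
        log_lines.append(stage + "\t" + "\t".join(f"{k}={v}" for k, v in kv.items()))

    def flush_summary(status: str) -> None:
        with open(out / "summary.json", "w") as fh:
            json.dump({"status": status, **counts}, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")

    try:
        bundle = _run_stages(cfg, out, note)
        bundle.counts = counts
        flush_summary("complete")
        return bundle
    except Exception:
        flush_summary("incomplete")
        raise


def _run_stages(cfg: RunConfig, out: Path, note) -> ReportBundle:
    d_a, d_b = cfg.diseases
    aliases = (
        ingest.parse_alias_table(cfg.path("aliases")) if cfg.path("aliases") else {}
    )

    # ---- ingest ----------------------------------------------------------
    gwas_path = cfg.path("gwas")
    n_raw = sum(
        1
        for line in open(gwas_path)
        if line.strip() and not line.startswith("#")
    ) - 1
    gwas_all = ingest.parse_gwas_table(gwas_path, cfg.trait_map)
    note("gwas", rows=n_raw, kept=len(gwas_all), dropped=n_raw - len(gwas_all))

    links_all = []
    for study, p in cfg.path("eqtl").items():
        links_all.extend(ingest.parse_eqtl_table(p, study))
    hpo_ann = ingest.parse_hpo_table(cfg.path("hpo"))
    expr = ingest.parse_expression_table(cfg.path("expression"))

    disease_sets: dict[str, DiseaseGeneSet] = {}
    drug_records = drugs.parse_drug_tables(cfg.path("drugs"), cfg.path("drug_targets"))
    groups: dict[tuple[str, str], drugs.DrugGroup] = {}
    paradoxical: dict[str, tuple[str, ...]] = {}
    links_kept_by_disease: dict[str, list] = {}
    gwas_by_disease: dict[str, list] = {}

    for disease in (d_a, d_b):
        icfg = cfg.ingest_config(disease)
        gw = [v for v in gwas_all if v.trait == disease]
        gwas_by_disease[disease] = gw
        coding = ingest.filter_coding_variants(gw, icfg)
        coding_genes = {v.mapped_gene: set() for v in coding if v.mapped_gene}
        for v in coding:
            if v.mapped_gene:
                coding_genes[v.mapped_gene].add(v.snp_id)
        note(f"coding_{disease}", variants=len(gw), kept=len(coding),
             dropped=len(gw) - len(coding))

        links_kept = ingest.filter_eqtl_fdr(links_all, icfg)
        links_kept_by_disease[disease] = links_kept
        eqtl_map = ingest.eqtl_regulated_genes(gw, links_kept)
        eqtl_detail = {
            g: {f"{snp}@{study}" for snp, study in pairs}
            for g, pairs in eqtl_map.items()
        }

        hpo_genes = ingest.select_hpo_genes(hpo_ann, icfg)
        curated = ingest.parse_curated_list(
            cfg.path("curated_monogenic"), disease, EvidenceChannel.MONOGENIC
        )
        mono = hpo_genes | ingest.curated_genes(curated)
        de = ingest.de_genes_min_support([r for r in expr if r.disease == disease], icfg)
        text_list = ingest.parse_curated_list(
            cfg.path("text_mining"), disease, EvidenceChannel.TEXT_MINING
        )
        text = ingest.text_mined_genes(text_list, icfg)

        grp = drugs.build_drug_groups(drug_records, disease)
        groups[(disease, "beneficial")] = grp.beneficial
        groups[(disease, "harmful")] = grp.harmful
        paradoxical[disease] = grp.paradoxical
        dt_detail: dict[str, set[str]] = {}
        for group in (grp.beneficial, grp.harmful):
            for gene, pairs in drugs.group_target_genes(group, drug_records).items():
                dt_detail.setdefault(gene, set()).update(
                    f"{drug}:{effect}" for drug, effect in pairs
                )

        disease_sets[disease] = ingest.assemble_disease_gene_set(
            disease,
            {
                EvidenceChannel.MONOGENIC: mono,
                EvidenceChannel.CODING_GWAS: coding_genes,
                EvidenceChannel.EQTL: eqtl_detail,
                EvidenceChannel.DIFF_EXPR: de,
                EvidenceChannel.TEXT_MINING: text,
                EvidenceChannel.DRUG_TARGET: dt_detail,
            },
            namespace=cfg.namespace,
            aliases=aliases,
        )
        ingest.write_association_table(
            disease_sets[disease], out / f"associations_{disease}.tsv"
        )
        note(
            f"channels_{disease}",
            **{
                ch.value: len(disease_sets[disease].with_channel(ch))
                for ch in CHANNELS
            },
            total=len(disease_sets[disease]),
        )

    note(
        "eqtl_filter",
        links=len(links_all),
        kept=len(links_kept_by_disease[d_a]),
        dropped=len(links_all) - len(links_kept_by_disease[d_a]),
    )

    # ---- universe and shared genes --------------------------------------
    universe: set[str] = set()
    universe |= {v.mapped_gene for v in gwas_all if v.mapped_gene}
    universe |= {l.gene for l in links_all}
    universe |= {a.gene for a in hpo_ann}
    universe |= {r.gene for r in expr}
    text_all = ingest._read_tsv(cfg.path("text_mining"), ("disease", "gene"))
    universe |= set(text_all["gene"])
    curated_all = ingest._read_tsv(cfg.path("curated_monogenic"), ("disease", "gene"))
    universe |= set(curated_all["gene"])
    universe |= {
        t.gene for rec in drug_records for t in rec.targets if t.human
    }
    universe = _norm_set(universe, cfg.namespace, aliases)
    universe |= set(disease_sets[d_a].genes) | set(disease_sets[d_b].genes)

    shared = core.shared_gene_table(disease_sets[d_a], disease_sets[d_b], universe)
    note("shared", n_a=len(disease_sets[d_a]), n_b=len(disease_sets[d_b]),
         shared=len(shared), universe=len(universe))

    novelty = None
    if cfg.path("references") is not None:
        ref_df = ingest._read_tsv(cfg.path("references"), ("reference", "gene"))
        refs: dict[str, set[str]] = {}
        for row in ref_df.itertuples(index=False):
            refs.setdefault(row.reference, set()).add(row.gene)
        novelty = core.novelty_flags(shared, sorted(refs.items()))
        note("novelty", novel=novelty.n_novel, known=len(shared) - novelty.n_novel)
    core.write_shared_table(shared, out / "shared_genes.tsv", novelty)

    # ---- network and modules --------------------------------------------
    net = network.build_network(shared, cfg.path("edges"))
    note("network", nodes=len(net), edges=net.graph.number_of_edges(),
         connectivity=round(net.connectivity, 4))
    cover = network.eagle(
        net,
        min_clique=int(cfg.thresholds["min_clique"]),
        min_complex=int(cfg.thresholds["min_complex"]),
        seed=cfg.seed,
    )
    note("modules", n=len(cover.modules), sizes=[len(m) for m in cover.modules],
         eq=round(cover.eq, 6))
    network.write_cover(cover, out / "modules.tsv", out / "modules.json")
    _export_graphml(net, out / "network.graphml")
    _export_edges(net, out / "network_edges.tsv")

    collections = (
        parse_gmt(cfg.path("collections")) if cfg.path("collections") else {}
    )
    alpha = float(cfg.thresholds["alpha"])
    annotations = network.annotate_modules(cover, shared, collections, alpha=alpha)
    _write_annotations(annotations, out / "module_annotations.tsv")

    # ---- drug statistics -------------------------------------------------
    cross_overlap = {
        f"{d_a}_beneficial_{d_b}_harmful": drugs.cross_disease_harm_overlap(
            groups[(d_a, "beneficial")], groups[(d_b, "harmful")]
        ),
        f"{d_b}_beneficial_{d_a}_harmful": drugs.cross_disease_harm_overlap(
            groups[(d_b, "beneficial")], groups[(d_a, "harmful")]
        ),
    }
    drug_background = {rec.drug_id for rec in drug_records}
    overlap_tests = {
        f"{d_a}_beneficial_{d_b}_harmful": stats.group_overlap_test(
            set(groups[(d_a, "beneficial")].drugs),
            set(groups[(d_b, "harmful")].drugs),
            drug_background,
        ),
        f"{d_b}_beneficial_{d_a}_harmful": stats.group_overlap_test(
            set(groups[(d_b, "beneficial")].drugs),
            set(groups[(d_a, "harmful")].drugs),
            drug_background,
        ),
    }
    drug_overrep = {}
    for key in sorted(groups):
        disease, polarity = key
        results = stats.drug_target_overrep(groups[key], drug_records, alpha=alpha)
        drug_overrep[key] = results
        _write_enrichment(results, out / f"drug_overrep_{disease}_{polarity}.tsv")
        note(f"drug_overrep_{disease}_{polarity}",
             drugs=len(groups[key].drugs),
             tested=len(results),
             significant=sum(r.significant for r in results))
    with open(out / "drug_overlap.json", "w") as fh:
        json.dump(
            {
                "overlap": cross_overlap,
                "paradoxical": {d: list(paradoxical[d]) for d in sorted(paradoxical)},
                "fisher_p": {k: overlap_tests[k].p for k in sorted(overlap_tests)},
            },
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")
    _write_drug_groups(groups, out / "drug_groups.tsv")

    # ---- channel enrichment and permutation ------------------------------
    channel_tests = {}
    with open(out / "channel_enrichment.tsv", "w") as fh:
        fh.write("channel\ta\tb\tc\td\todds_ratio\tp\tdegenerate\n")
        for ch in CHANNELS:
            res = core.channel_enrichment(
                shared, ch, disease_sets[d_a], disease_sets[d_b]
            )
            channel_tests[ch] = res
            fh.write(
                f"{ch.value}\t{res.a}\t{res.b}\t{res.c}\t{res.d}"
                f"\t{res.odds_ratio:.6g}\t{res.p:.6g}\t{res.degenerate}\n"
            )

    links_kept = links_kept_by_disease[d_a]
    snp_universe = {l.snp_id for l in links_kept}
    snps_a = {v.snp_id for v in gwas_by_disease[d_a]} & snp_universe
    snps_b = {v.snp_id for v in gwas_by_disease[d_b]} & snp_universe
    permutation = stats.matched_permutation(
        links_kept, snps_a, snps_b,
        n_perm=int(cfg.thresholds["n_perm"]), seed=cfg.seed,
    )
    note("permutation", observed=permutation.observed,
         null_mean=round(permutation.null_mean, 3),
         p=permutation.p_empirical, n_perm=permutation.n_perm,
         snps_a=len(snps_a), snps_b=len(snps_b), snp_universe=len(snp_universe))
    with open(out / "permutation.json", "w") as fh:
        json.dump(
            {
                "observed": permutation.observed,
                "n_perm": permutation.n_perm,
                "null_mean": permutation.null_mean,
                "null_ge_observed": permutation.null_ge_observed,
                "p_empirical": permutation.p_empirical,
            },
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")

    return ReportBundle(
        config_hash=cfg.config_hash,
        disease_sets=disease_sets,
        shared=shared,
        novelty=novelty,
        net=net,
        cover=cover,
        annotations=annotations,
        drug_groups=groups,
        paradoxical=paradoxical,
        cross_overlap=cross_overlap,
        overlap_tests=overlap_tests,
        drug_overrep=drug_overrep,
        channel_tests=channel_tests,
        permutation=permutation,
        counts={},
    )


def _export_graphml(net: network.Network, path) -> None:
    g = nx.Graph()
    g.add_nodes_from(sorted(net.graph.nodes))
    for u, v, data in sorted(net.graph.edges(data=True)):
        attrs = {"types": ";".join(sorted(data.get("types", set())))}
        if data.get("weight") is not None:
            attrs["weight"] = float(data["weight"])
        g.add_edge(u, v, **attrs)
    nx.write_graphml(g, path)


def _export_edges(net: network.Network, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene1\tgene2\ttypes\tweight\n")
        for u, v, data in sorted(net.graph.edges(data=True)):
            u, v = sorted((u, v))
            types = ";".join(sorted(data.get("types", set())))
            w = data.get("weight")
            fh.write(f"{u}\t{v}\t{types}\t{'' if w is None else w}\n")


def _write_enrichment(results, path) -> None:
    with open(path, "w") as fh:
        fh.write("item\tk\tK\tn\tN\tp\tq\tsignificant\n")
        for r in results:
            fh.write(
                f"{r.term}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t{r.p:.6g}\t{r.q:.6g}"
                f"\t{'yes' if r.significant else 'no'}\n"
            )


def _write_annotations(annotations, path) -> None:
    with open(path, "w") as fh:
        header = ["module_id", "size"] + [ch.value for ch in CHANNELS] + [
            "significant_terms"
        ]
        fh.write("\t".join(header) + "\n")
        for ann in annotations:
            terms = ";".join(r.term for r in ann.enrichment if r.significant)
            row = [str(ann.module_id), str(ann.size)] + [
                str(ann.channel_counts[ch]) for ch in CHANNELS
            ] + [terms]
            fh.write("\t".join(row) + "\n")


def _write_drug_groups(groups, path) -> None:
    with open(path, "w") as fh:
        fh.write("disease\tpolarity\tdrug_id\n")
        for key in sorted(groups):
            disease, polarity = key
            for drug_id in sorted(groups[key].drugs):
                fh.write(f"{disease}\t{polarity}\t{drug_id}\n")
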