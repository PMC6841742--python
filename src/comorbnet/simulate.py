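"""Synthetic input generator with planted, parameterized structure.

Every table the pipeline consumes is emulated here: a GWAS-catalog-style
variant table, per-study eQTL link tables, phenotype-ontology annotations,
differential-expression reports, text-mining gene lists, drug and
drug-target tables, a typed gene-gene edge list, gene-set collections (GMT),
reference gene-disease sets and an alias table. The generator plants the
quantities the analysis is meant to recover — shared genes, an excess of
genes co-regulated by both diseases' eQTLs, beneficial/harmful drug overlaps
with overrepresented targets, and clique modules on the network — and
records the full planted truth in a manifest so end-to-end recovery is
machine-checkable. Output is deterministic given the spec (including seed).

Structural note: disease-specific genes draw evidence channels only for
their own disease, so the planted shared genes are exactly the genes
associated with both diseases; noise enters through edge wiring, decoy rows
and the random components of each table rather than through cross-disease
label collisions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .errors import InfeasibleSpecError
from .stats import matched_permutation, sample_matched_pair
from .types import EqtlLink

__all__ = ["FixtureSpec", "gen_fixture", "gen_null_eqtl_pair", "load_spec"]

_CODING = (
    "missense_variant",
    "splice_region_variant",
    "synonymous_variant",
    "non_coding_transcript_exon_variant",
)
_EDGE_TYPES = ("coexpression", "physical", "pathway")
_HPO_INCLUDE = {
    0: ("HP:0002099", "HP:0012042"),
    1: ("HP:0000822", "HP:0004421"),
}
_HPO_EXCLUDE = {0: (), 1: ("HP:0007906",)}


@dataclass
class FixtureSpec:
    """Parameters of one synthetic study world.

    Defaults emulate the statistical structure of a two-disease comorbidity
    study at desk scale: a large gene universe with a planted shared core,
    text mining as the dominant evidence channel, an eQTL channel with trans
    fan-out and a deliberate excess of co-regulated shared genes, four drug
    groups with planted overrepresented targets and treat-one/harm-other
    drugs, and clique modules on the shared-gene network.
    """

    n_genes: int = 2000
    n_snps: int = 600
    diseases: tuple[str, str] = ("asthma", "hypertension")
    planted_shared: int = 60
    per_channel_rates: dict[str, float] = field(
        default_factory=lambda: {
            "monogenic": 0.10,
            "coding_gwas": 0.08,
            "eqtl": 0.15,
            "diff_expr": 0.25,
            "text_mining": 0.70,
        }
    )
    eqtl_fanout_mean: float = 2.0
    planted_eqtl_excess: int = 25
    n_eqtl_core_snps: int = 1
    n_drugs: int = 240
    drug_group_sizes: tuple[int, int, int, int] = (18, 20, 25, 22)
    planted_cross_drugs: int = 7
    n_paradoxical: int = 2
    n_overrep_targets: int = 3
    module_spec: list[tuple[int, int]] = field(default_factory=lambda: [(12, 4)])
    noise_edge_p: float = 0.02
    frac_disease_only: float = 0.30
    n_eqtl_a: int = 150
    n_eqtl_b: int = 120
    n_eqtl_shared: int = 2
    seed: int = 0

    def validate(self) -> None:
        module_genes = sum(size * count for size, count in self.module_spec)
        checks = [
            (self.planted_shared <= self.n_genes, "planted_shared exceeds n_genes"),
            (
                self.planted_eqtl_excess + self.planted_cross_drugs
                <= self.planted_shared,
                "eQTL excess plus cross-drug target genes exceed planted_shared",
            ),
            (module_genes <= self.planted_shared,
             "module_spec needs more genes than planted_shared"),
            (all(0 <= r <= 1 for r in self.per_channel_rates.values()),
             "channel rates must lie in [0, 1]"),
            (0 <= self.noise_edge_p < 1, "noise_edge_p must lie in [0, 1)"),
            (self.drug_group_sizes[0]
             > self.planted_cross_drugs + self.n_paradoxical,
             "beneficial group of disease A too small for planted cross and "
             "paradoxical drugs"),
            (self.drug_group_sizes[3] > self.planted_cross_drugs,
             "harmful group of disease B too small for planted cross drugs"),
            (sum(self.drug_group_sizes) - self.planted_cross_drugs + 20
             <= self.n_drugs,
             "n_drugs too small for the requested groups plus background"),
            (self.n_eqtl_a + self.n_eqtl_b - self.n_eqtl_shared <= self.n_snps,
             "null eQTL set sizes exceed the SNP universe"),
            (self.eqtl_fanout_mean >= 1.0, "eqtl_fanout_mean must be >= 1"),
        ]
        for ok, msg in checks:
            if not ok:
                raise InfeasibleSpecError(msg)


def load_spec(path) -> FixtureSpec:
    """Read a FixtureSpec from a YAML file (missing keys take defaults)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = set(FixtureSpec.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise InfeasibleSpecError(f"unknown spec key(s): {sorted(unknown)}")
    if "diseases" in data:
        data["diseases"] = tuple(data["diseases"])
    if "module_spec" in data:
        data["module_spec"] = [tuple(x) for x in data["module_spec"]]
    if "drug_group_sizes" in data:
        data["drug_group_sizes"] = tuple(data["drug_group_sizes"])
    return FixtureSpec(**data)


def _truncated_geometric(rng: np.random.Generator, mean: float, cap: int = 8) -> int:
    if mean <= 1.0:
        return 1
    f = 1 + rng.geometric(1.0 / mean)
    return int(min(f, cap))


def _tsv(path: Path, header: list[str], rows: list[tuple]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def gen_fixture(spec: FixtureSpec, out_dir) -> dict:
    """Write all pipeline inputs plus manifest.json and config.yaml.

    Returns the manifest (also written to ``out_dir``). The spec is validated
    before any file is written; an infeasible spec leaves the directory
    untouched.
    """
    spec.validate()
    out = Path(out_dir)
    rng = np.random.default_rng(spec.seed)
    d_a, d_b = spec.diseases

    # ---- gene pools ------------------------------------------------------
    genes = [f"G{i:04d}" for i in range(1, spec.n_genes + 1)]
    perm = [genes[i] for i in rng.permutation(spec.n_genes)]
    shared = sorted(perm[: spec.planted_shared])
    remaining = perm[spec.planted_shared :]
    n_only = int(len(remaining) * spec.frac_disease_only)
    a_only = sorted(remaining[:n_only])
    b_only = sorted(remaining[n_only : 2 * n_only])
    bg_pool = sorted(remaining[2 * n_only :])
    if len(bg_pool) < 450:
        raise InfeasibleSpecError(
            "background gene pool too small (<450); increase n_genes or lower "
            "frac_disease_only"
        )

    excess = shared[: spec.planted_eqtl_excess]
    dt_both = shared[
        spec.planted_eqtl_excess : spec.planted_eqtl_excess + spec.planted_cross_drugs
    ]

    # ---- evidence channel truth -----------------------------------------
    chan: dict[str, dict[str, set[str]]] = {d_a: {}, d_b: {}}

    def add(d: str, g: str, ch: str) -> None:
        chan[d].setdefault(g, set()).add(ch)

    rates = spec.per_channel_rates
    for disease, pool in ((d_a, a_only + shared), (d_b, b_only + shared)):
        for g in sorted(pool):
            for ch in ("monogenic", "coding_gwas", "diff_expr", "text_mining"):
                if rng.random() < rates.get(ch, 0.0):
                    add(disease, g, ch)
            if g in excess or rng.random() < rates.get("eqtl", 0.0):
                add(disease, g, "eqtl")

    # ---- drugs -----------------------------------------------------------
    drug_ids = [f"D{i:04d}" for i in range(1, spec.n_drugs + 1)]
    b_a, h_a, b_b, h_b = spec.drug_group_sizes
    it = iter(drug_ids)
    cross = [next(it) for _ in range(spec.planted_cross_drugs)]
    paradox = [next(it) for _ in range(spec.n_paradoxical)]
    benef_a_rest = [next(it) for _ in range(b_a - len(cross) - len(paradox))]
    harm_a = [next(it) for _ in range(h_a)]
    benef_b = [next(it) for _ in range(b_b)]
    harm_b_rest = [next(it) for _ in range(h_b - len(cross))]
    background_drugs = list(it)

    relations: dict[str, dict[str, set[str]]] = {
        d: {"indicated": set(), "contraindicated": set(), "adverse_inducing": set()}
        for d in drug_ids
    }
    for i, d in enumerate(cross):
        relations[d]["indicated"].add(d_a)
        key = "adverse_inducing" if i % 2 == 0 else "contraindicated"
        relations[d][key].add(d_b)
    for d in paradox:
        relations[d]["indicated"].add(d_a)
        relations[d]["contraindicated"].add(d_a)
    for d in benef_a_rest:
        relations[d]["indicated"].add(d_a)
    for i, d in enumerate(harm_a):
        key = "adverse_inducing" if i % 2 == 0 else "contraindicated"
        relations[d][key].add(d_a)
    for d in benef_b:
        relations[d]["indicated"].add(d_b)
    for i, d in enumerate(harm_b_rest):
        key = "adverse_inducing" if i % 2 == 0 else "contraindicated"
        relations[d][key].add(d_b)

    groups = {
        (d_a, "beneficial"): sorted(cross + paradox + benef_a_rest),
        (d_a, "harmful"): sorted(harm_a),
        (d_b, "beneficial"): sorted(benef_b),
        (d_b, "harmful"): sorted(cross + harm_b_rest),
    }

    # planted overrepresented target genes per group, from disease-only pools
    overrep: dict[tuple[str, str], list[str]] = {}
    a_dt_pool = [g for g in a_only if g not in chan[d_a]] + [
        g for g in a_only if g in chan[d_a]
    ]
    b_dt_pool = [g for g in b_only if g not in chan[d_b]] + [
        g for g in b_only if g in chan[d_b]
    ]
    ai, bi = 0, 0
    for key in sorted(groups):
        disease = key[0]
        if disease == d_a:
            overrep[key] = sorted(a_dt_pool[ai : ai + spec.n_overrep_targets])
            ai += spec.n_overrep_targets
        else:
            overrep[key] = sorted(b_dt_pool[bi : bi + spec.n_overrep_targets])
            bi += spec.n_overrep_targets

    pos_actions = ("agonist", "activator")
    neg_actions = ("antagonist", "inhibitor")
    target_rows: list[tuple] = []  # drug_id, gene, action_raw, organism

    def group_actions(polarity: str) -> tuple[str, ...]:
        return pos_actions if polarity == "beneficial" else neg_actions

    sporadic_counter = {d_a: 0, d_b: 0}
    sporadic_pools = {d_a: a_dt_pool[4 * spec.n_overrep_targets :], d_b: b_dt_pool[4 * spec.n_overrep_targets :]}
    cross_set = set(cross)
    for key in sorted(groups):
        disease, polarity = key
        members = groups[key]
        non_cross = [d for d in members if d not in cross_set]
        n_hit = max(2, int(np.ceil(0.8 * len(non_cross))))
        actions = group_actions(polarity)
        for t_gene in overrep[key]:
            for j, drug in enumerate(non_cross[:n_hit]):
                target_rows.append((drug, t_gene, actions[j % 2], "Human"))
            add(disease, t_gene, "drug_target")
        # one sporadic target per non-cross member drug
        for j, drug in enumerate(non_cross):
            pool = sporadic_pools[disease]
            g = pool[sporadic_counter[disease] % len(pool)]
            sporadic_counter[disease] += 1
            target_rows.append((drug, g, actions[j % 2], "Human"))
            add(disease, g, "drug_target")
    # cross drugs target their own planted shared gene only
    for drug, g in zip(cross, dt_both):
        target_rows.append((drug, g, "agonist", "Human"))
        add(d_a, g, "drug_target")
        add(d_b, g, "drug_target")
    # background drugs target background-pool genes
    bg_target_pool = bg_pool[: max(120, 3 * len(background_drugs) // 2)]
    all_actions = pos_actions + neg_actions + ("modifier",)
    for i, drug in enumerate(background_drugs):
        n_t = 1 + int(rng.integers(0, 3))
        for j in range(n_t):
            g = bg_target_pool[int(rng.integers(0, len(bg_target_pool)))]
            target_rows.append((drug, g, all_actions[int(rng.integers(0, 5))], "Human"))
    # non-human decoy targets (never emitted by the target logic)
    decoy_hosts = groups[(d_a, "beneficial")][:2] + background_drugs[:2]
    for i, drug in enumerate(decoy_hosts):
        target_rows.append((drug, f"NHG{i:02d}", "inhibitor", "Mouse"))

    # guarantee the shared genes carry evidence for both diseases
    for g in shared:
        for disease in (d_a, d_b):
            if not chan[disease].get(g):
                add(disease, g, "text_mining")

    # ---- eQTL structure --------------------------------------------------
    snp_counter = [0]

    def new_snp() -> str:
        snp_counter[0] += 1
        if snp_counter[0] > spec.n_snps:
            raise InfeasibleSpecError(
                "SNP universe exhausted; increase n_snps or lower channel rates"
            )
        return f"rs{snp_counter[0]:06d}"

    core_snps = [new_snp() for _ in range(spec.n_eqtl_core_snps)]
    n_core_genes = (len(excess) + 1) // 2 if core_snps else 0
    x_core = excess[:n_core_genes]
    x_pair = excess[n_core_genes:]

    links: list[tuple[str, str, str, str, float]] = []  # snp, gene, tissue, kind, fdr
    studies = ("bluemeta", "gtexlike")
    tissues = ("whole_blood", "lung", "aorta")
    link_keys: set[tuple[str, str]] = set()

    def add_link(snp: str, gene: str, kind: str, fdr: float) -> None:
        if (snp, gene) in link_keys:
            return
        link_keys.add((snp, gene))
        tissue = tissues[int(rng.integers(0, len(tissues)))]
        links.append((snp, gene, tissue, kind, round(float(fdr), 6)))

    if core_snps:
        for i, g in enumerate(x_core):
            add_link(core_snps[i % len(core_snps)], g, "trans", rng.uniform(0.0, 0.049))

    reg_snps = {d_a: list(core_snps), d_b: list(core_snps)}
    for disease in (d_a, d_b):
        to_place = sorted(
            g for g, chs in chan[disease].items() if "eqtl" in chs and g not in x_core
        )
        i = 0
        while i < len(to_place):
            f = _truncated_geometric(rng, spec.eqtl_fanout_mean)
            snp = new_snp()
            reg_snps[disease].append(snp)
            chunk = to_place[i : i + f]
            kind = "cis" if len(chunk) == 1 else "trans"
            for g in chunk:
                add_link(snp, g, kind, rng.uniform(0.0, 0.049))
            i += f
    # one boundary link at exactly the FDR threshold (kept: inclusive rule)
    if reg_snps[d_a][len(core_snps):]:
        snp = reg_snps[d_a][len(core_snps)]
        gene = next(g for (s, g, _t, _k, _f) in links if s == snp)
        links.append((snp, gene, "skin", "cis", 0.05))
    # decoy links failing the FDR filter, from real regulatory SNPs
    for i in range(8):
        pool = reg_snps[d_a] if i % 2 == 0 else reg_snps[d_b]
        snp = pool[int(rng.integers(0, len(pool)))]
        gene = bg_pool[200 + i]
        add_link(snp, gene, "cis", rng.uniform(0.06, 0.9))
    # decoy SNPs absent from GWAS: widen the permutation universe only
    for i in range(20):
        snp = new_snp()
        for j in range(_truncated_geometric(rng, spec.eqtl_fanout_mean)):
            gene = bg_pool[230 + ((7 * i + j) % 200)]
            add_link(snp, gene, "cis", rng.uniform(0.0, 0.049))

    # ---- GWAS table ------------------------------------------------------
    trait_labels = {
        d_a: (d_a, f"{d_a}_related_trait"),
        d_b: (d_b, f"{d_b}_related_trait"),
    }
    gwas_rows: list[tuple] = []  # snp_id, trait, p_value, consequence, mapped_gene
    coding_snps: dict[str, list[str]] = {d_a: [], d_b: []}
    for disease in (d_a, d_b):
        for g in sorted(g for g, chs in chan[disease].items() if "coding_gwas" in chs):
            snp = new_snp()
            coding_snps[disease].append(snp)
            trait = trait_labels[disease][int(rng.integers(0, 2))]
            p = 10 ** rng.uniform(-12, -5.05)
            cons = _CODING[int(rng.integers(0, len(_CODING)))]
            gwas_rows.append((snp, trait, f"{p:.3e}", cons, g))
        for snp in reg_snps[disease]:
            trait = trait_labels[disease][0]
            p = 10 ** rng.uniform(-8, -5.05)
            gwas_rows.append((snp, trait, f"{p:.3e}", "intron_variant", ""))
    # decoys: unmapped traits, boundary p-values, non-coding consequences
    for i in range(3):
        gwas_rows.append((new_snp(), "height", "1.000e-08", "missense_variant", bg_pool[i]))
    gwas_rows.append((new_snp(), d_a, "1.000e-05", "missense_variant", bg_pool[3]))
    gwas_rows.append((new_snp(), d_b, "2.000e-05", "missense_variant", bg_pool[4]))
    gwas_rows.append((new_snp(), d_a, "1.000e-07", "intergenic_variant", bg_pool[5]))

    # ---- HPO and curated monogenic lists --------------------------------
    include = {d_a: _HPO_INCLUDE[0], d_b: _HPO_INCLUDE[1]}
    exclude = {d_a: _HPO_EXCLUDE[0], d_b: _HPO_EXCLUDE[1]}
    hpo_rows: list[tuple] = []
    curated_rows: list[tuple] = []
    for disease in (d_a, d_b):
        mono = sorted(g for g, chs in chan[disease].items() if "monogenic" in chs)
        n_hpo = int(np.ceil(0.6 * len(mono)))
        for g in mono[:n_hpo]:
            term = include[disease][int(rng.integers(0, len(include[disease])))]
            hpo_rows.append((g, term, "frequent"))
        for g in mono[:3]:
            if exclude[disease]:
                hpo_rows.append((g, exclude[disease][0], "frequent"))
        for g in mono[n_hpo:]:
            curated_rows.append((disease, g, 1 + int(rng.integers(0, 3))))
    for i in range(3):
        hpo_rows.append((bg_pool[10 + i], include[d_a][0], "occasional"))
    for i in range(3):
        if exclude[d_b]:
            hpo_rows.append((bg_pool[20 + i], exclude[d_b][0], "frequent"))

    # ---- expression reports ---------------------------------------------
    expr_rows: list[tuple] = []
    for disease in (d_a, d_b):
        de = sorted(g for g, chs in chan[disease].items() if "diff_expr" in chs)
        n_sig = len(de) // 2
        for g in de[:n_sig]:
            direction = "up" if rng.random() < 0.5 else "down"
            expr_rows.append((g, disease, direction, f"signature_{disease}", "true"))
        for g in de[n_sig:]:
            direction = "up" if rng.random() < 0.5 else "down"
            expr_rows.append((g, disease, direction, "andsystem", "false"))
            expr_rows.append((g, disease, direction, "disgenet", "false"))
    for i in range(3):
        expr_rows.append((bg_pool[30 + i], d_a, "up", "andsystem", "false"))
    for i in range(2):
        expr_rows.append((bg_pool[40 + i], d_b, "down", "disgenet", "false"))
        expr_rows.append((bg_pool[40 + i], d_b, "up", "disgenet", "false"))

    # ---- text mining -----------------------------------------------------
    text_rows: list[tuple] = []
    alias_rows: list[tuple] = [("alias", "canonical")]
    aliased_gene: Optional[str] = None
    for disease in (d_a, d_b):
        tm = sorted(g for g, chs in chan[disease].items() if "text_mining" in chs)
        for g in tm:
            label = g
            if disease == d_a and aliased_gene is None:
                aliased_gene = g
                label = f"{g.lower()}_syn"
                alias_rows.append((label, g))
            text_rows.append((disease, label, 2 + int(rng.integers(0, 18))))
    for i in range(4):
        text_rows.append((d_a, bg_pool[50 + i], 1))

    # ---- network edges and modules --------------------------------------
    modules: list[list[str]] = []
    cursor = 0
    for size, count in spec.module_spec:
        for _ in range(count):
            modules.append(shared[cursor : cursor + size])
            cursor += size
    module_of: dict[str, int] = {}
    for mi, mod in enumerate(modules):
        for g in mod:
            module_of[g] = mi
    edge_rows: list[tuple] = []
    for mod in modules:
        for i in range(len(mod)):
            for j in range(i + 1, len(mod)):
                etype = _EDGE_TYPES[int(rng.integers(0, 3))]
                edge_rows.append((mod[i], mod[j], etype, f"{rng.uniform(0.3, 1.0):.3f}"))
    if spec.noise_edge_p > 0:
        for i in range(len(shared)):
            for j in range(i + 1, len(shared)):
                gi, gj = shared[i], shared[j]
                if module_of.get(gi) is not None and module_of.get(gi) == module_of.get(gj):
                    continue
                if rng.random() < spec.noise_edge_p:
                    etype = _EDGE_TYPES[int(rng.integers(0, 3))]
                    edge_rows.append((gi, gj, etype, f"{rng.uniform(0.3, 1.0):.3f}"))
        # decoy edges outside the shared set, plus a duplicate typed edge
        for i in range(5):
            edge_rows.append((shared[i], bg_pool[60 + i], "physical", "0.500"))
        for i in range(3):
            edge_rows.append((bg_pool[70 + i], bg_pool[80 + i], "pathway", "0.500"))
        if modules:
            u, v = modules[0][0], modules[0][1]
            existing = next(r[2] for r in edge_rows if {r[0], r[1]} == {u, v})
            other = next(t for t in _EDGE_TYPES if t != existing)
            edge_rows.append((u, v, other, "0.500"))
        edge_rows.append((shared[0], shared[0], "physical", "0.500"))

    # ---- gene-set collections (GMT) -------------------------------------
    gmt_lines: list[str] = []
    for mi, mod in enumerate(modules, start=1):
        gmt_lines.append("\t".join([f"planted_module_{mi}", "planted"] + list(mod)))
    mix_pool = shared + bg_pool[:300]
    for i in range(8):
        size = 10 + int(rng.integers(0, 21))
        members = sorted(
            {mix_pool[int(rng.integers(0, len(mix_pool)))] for _ in range(size)}
        )
        gmt_lines.append("\t".join([f"random_set_{i + 1}", "decoy"] + members))

    # ---- reference gene-disease sets (novelty) ---------------------------
    ref_rows: list[tuple] = []
    ref_known: set[str] = set()
    for name in ("opentargets_like", "disgenet_like"):
        covered = [g for g in shared if rng.random() < 0.55]
        ref_known.update(covered)
        n_fill = min(60, len(a_only), len(b_only))
        filler = a_only[:n_fill] + b_only[:n_fill]
        for g in sorted(set(covered) | set(filler)):
            ref_rows.append((name, g))
    novel = sorted(set(shared) - ref_known)

    # ---- write everything ------------------------------------------------
    out.mkdir(parents=True, exist_ok=True)
    _tsv(out / "gwas.tsv", ["snp_id", "trait", "p_value", "consequence", "mapped_gene"], gwas_rows)
    study_files = {}
    for si, study in enumerate(studies):
        rows = [
            (snp, gene, tissue, kind, fdr)
            for i, (snp, gene, tissue, kind, fdr) in enumerate(links)
            if i % len(studies) == si
        ]
        fname = f"eqtl_{study}.tsv"
        study_files[study] = fname
        _tsv(out / fname, ["snp_id", "gene", "tissue", "kind", "fdr"], rows)
    _tsv(out / "hpo.tsv", ["gene", "term_id", "frequency_label"], hpo_rows)
    _tsv(out / "curated_monogenic.tsv", ["disease", "gene", "support_count"], curated_rows)
    _tsv(out / "expression.tsv", ["gene", "disease", "direction", "source", "trusted"], expr_rows)
    _tsv(out / "text_mining.tsv", ["disease", "gene", "support_count"], text_rows)
    drug_rows = [
        (
            d,
            f"drug{d[1:]}",
            ";".join(sorted(relations[d]["indicated"])),
            ";".join(sorted(relations[d]["contraindicated"])),
            ";".join(sorted(relations[d]["adverse_inducing"])),
        )
        for d in drug_ids
    ]
    _tsv(out / "drugs.tsv", ["drug_id", "name", "indicated", "contraindicated", "adverse_inducing"], drug_rows)
    _tsv(out / "drug_targets.tsv", ["drug_id", "gene", "action_raw", "organism"], target_rows)
    _tsv(out / "edges.tsv", ["gene1", "gene2", "type", "weight"], edge_rows)
    (out / "collections.gmt").write_text("\n".join(gmt_lines) + "\n")
    _tsv(out / "references.tsv", ["reference", "gene"], ref_rows)
    with open(out / "aliases.tsv", "w") as fh:
        for row in alias_rows:
            fh.write("\t".join(row) + "\n")

    # expected sharing under the matched null, for reference in the manifest
    link_objs = [
        EqtlLink(snp_id=s, gene=g, study="pooled", tissue=t, kind=k, fdr=f)
        for s, g, t, k, f in links
        if f <= 0.05
    ]
    snps_a = set(reg_snps[d_a]) | set(coding_snps[d_a])
    snps_b = set(reg_snps[d_b]) | set(coding_snps[d_b])
    universe = {l.snp_id for l in link_objs}
    perm_res = matched_permutation(
        link_objs,
        snps_a & universe,
        snps_b & universe,
        n_perm=300,
        seed=int(spec.seed) + 1,
    )

    manifest = {
        "spec": {**asdict(spec), "diseases": list(spec.diseases)},
        "diseases": [d_a, d_b],
        "genes": {d: sorted(chan[d]) for d in (d_a, d_b)},
        "shared": shared,
        "channels": {
            d: {g: sorted(chs) for g, chs in sorted(chan[d].items())}
            for d in (d_a, d_b)
        },
        "modules": [sorted(m) for m in modules],
        "cross_drugs": {
            f"{d_a}_beneficial_{d_b}_harmful": sorted(cross),
            f"{d_b}_beneficial_{d_a}_harmful": [],
        },
        "paradoxical": {d_a: sorted(paradox), d_b: []},
        "overrep_targets": {
            f"{d}:{pol}": overrep[(d, pol)] for d, pol in sorted(overrep)
        },
        "novel": novel,
        "eqtl": {
            "core_snps": core_snps,
            "n_snps_a": len(snps_a & universe),
            "n_snps_b": len(snps_b & universe),
            "shared_regulated_genes": sorted(
                g for g, chs in chan[d_a].items()
                if "eqtl" in chs and "eqtl" in chan[d_b].get(g, set())
            ),
            "observed_shared_regulated": perm_res.observed,
            "expected_null_mean": perm_res.null_mean,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    config = {
        "diseases": [d_a, d_b],
        "paths": {
            "gwas": "gwas.tsv",
            "eqtl": {s: f for s, f in sorted(study_files.items())},
            "hpo": "hpo.tsv",
            "curated_monogenic": "curated_monogenic.tsv",
            "expression": "expression.tsv",
            "text_mining": "text_mining.tsv",
            "drugs": "drugs.tsv",
            "drug_targets": "drug_targets.tsv",
            "edges": "edges.tsv",
            "collections": "collections.gmt",
            "references": "references.tsv",
            "aliases": "aliases.tsv",
        },
        "trait_map": {
            d_a: d_a,
            f"{d_a}_related_trait": d_a,
            d_b: d_b,
            f"{d_b}_related_trait": d_b,
        },
        "hpo_terms": {
            d_a: {"include": list(include[d_a]), "exclude": list(exclude[d_a])},
            d_b: {"include": list(include[d_b]), "exclude": list(exclude[d_b])},
        },
        "thresholds": {
            "gwas_p_max": 1.0e-5,
            "eqtl_fdr_max": 0.05,
            "de_min_sources": 2,
            "text_min_studies": 2,
            "min_clique": 10,
            "min_complex": 10,
            "alpha": 0.05,
            "n_perm": 2000,
        },
        "seed": int(spec.seed),
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return manifest


def gen_null_eqtl_pair(
    spec: FixtureSpec, seed: Optional[int] = None
) -> tuple[set[str], set[str], list[EqtlLink]]:
    """One null world: two SNP sets with the spec's sizes and intersection,
    drawn independently of the SNP-to-gene map.

    Used to calibrate the matched permutation test: since A and B are drawn
    by the very sampler the null uses, the empirical p-value should be
    (approximately) uniform over repeated worlds.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    snps = [f"rs{i:06d}" for i in range(1, spec.n_snps + 1)]
    genes = [f"G{i:04d}" for i in range(1, spec.n_genes + 1)]
    links: list[EqtlLink] = []
    for snp in snps:
        f = _truncated_geometric(rng, spec.eqtl_fanout_mean)
        picked = rng.choice(len(genes), size=min(f, len(genes)), replace=False)
        for gi in sorted(int(x) for x in picked):
            links.append(
                EqtlLink(
                    snp_id=snp, gene=genes[gi], study="null", tissue="whole_blood",
                    kind="cis" if f == 1 else "trans", fdr=0.01,
                )
            )
    idx_a, idx_b = sample_matched_pair(
        rng, len(snps), spec.n_eqtl_a, spec.n_eqtl_b, spec.n_eqtl_shared
    )
    snps_a = {snps[int(i)] for i in idx_a}
    snps_b = {snps[int(i)] for i in idx_b}
    return snps_a, snps_b, links
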