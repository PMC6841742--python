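# Methods

This note documents the models and procedures implemented in `comorbnet`,
the parameters that matter, what the synthetic-data generator does and does
not emulate, the numerical choices, and known limitations.

## Evidence integration

One gene set per disease is assembled from six channels. The filters, their
defaults and their boundary semantics:

| channel | rule | default | boundary |
|---|---|---|---|
| `coding_gwas` | variant p-value below threshold AND consequence in the coding class set | `gwas_p_max = 1e-5`; consequences: splice_region, missense, synonymous, non_coding_transcript_exon | strict `<` (a variant at exactly 1e-5 is dropped) |
| `eqtl` | gene regulated by ≥ 1 disease-associated GWAS SNP via an FDR-passing link | `eqtl_fdr_max = 0.05` | inclusive `≤` ("passed the threshold") |
| `monogenic` | phenotype annotation to an included term with the *frequent* label, or membership in a curated syndrome list | labels `{frequent}`; curated min support 1 | exclusion removes *annotations*, not genes: a gene annotated to both an included and an excluded term stays in |
| `diff_expr` | ≥ 1 trusted signature report, or reports from ≥ `de_min_sources` distinct untrusted sources | 2 | distinctness by source label, not row count |
| `text_mining` | support count ≥ `text_min_studies` | 2 | — |
| `drug_target` | human target of any drug in the disease's beneficial or harmful group | organism ∈ {Human, Homo sapiens}, case-insensitive | non-human targets are never emitted |

Two channel-design points deserve emphasis. First, the eQTL channel maps
**all** GWAS variants of a disease, not only coding ones — the
transcript-consequence filter belongs to the coding channel alone, because
regulatory variants are exactly the ones expected to act through
expression. Second, one gene namespace (HGNC-style symbols, upper-cased, or
purely numeric IDs) is declared per run with an optional alias table;
identifiers that look like the other namespace raise instead of being
silently merged, since cross-source symbol/ID mixtures are a classic silent
corruption.

## Drug groups

For each disease: *beneficial* = indicated drugs; *harmful* = contraindicated
∪ adverse-inducing (one pooled polarity — the two flags are preserved in
provenance but behave identically downstream). A drug appearing on both
sides for the same disease is a paradoxical-reaction case and is removed
from the harmful group only, on the grounds that paradoxical reactions are
rare relative to the intended effect. Raw action vocabularies collapse to
three effects — positive (agonist, activator, inducer, potentiator, partial
agonist, stimulator), negative (antagonist, inhibitor, blocker, suppressor),
other (modifier, ligand, binder, unknown) — via a case-insensitive,
user-overridable table; unknown terms raise by default (policy `other`
available with a logged warning).

## Shared genes and enrichment background

The shared-gene table contains exactly the intersection of the two disease
sets, sorted by combined evidence count (descending) then gene name, so
output order is total and reproducible. The enrichment "universe" defaults
to every gene attested anywhere in the run's inputs (GWAS-mapped genes, all
eQTL link genes, all phenotype-annotated genes, all expression-report genes,
all text-mining and curated entries regardless of support, and all human
drug targets). Co-association p-values depend strongly on this choice, so
the universe is configurable and its size is reported in every summary.

## Overlapping module detection

The detector follows the clique-seeded agglomerative scheme with an
extended-modularity cut:

1. enumerate maximal cliques (Bron–Kerbosch via networkx); discard cliques
   smaller than `min_clique`;
2. every node outside all retained cliques becomes a singleton community;
3. repeatedly merge the community pair with maximal similarity
   `S(C1,C2) = (1/2m) Σ_{v∈C1\C2, w∈C2\C1} [A_vw − k_v k_w/2m]`, recording
   the dendrogram, until one community remains per connected component
   (cross-component merges are forbidden — their similarity is ≤ 0 and
   meaningless);
4. evaluate `EQ` at every dendrogram level and return the maximizing cover;
5. drop modules smaller than `min_complex` from the report (they remain in
   the dendrogram).

`EQ` sums `[A_vw − k_v k_w/2m] / (O_v O_w)` over ordered member pairs
*including* the diagonal null term, which is what makes the all-in-one cover
of a connected graph score exactly 0. Membership counts `O_v` treat genes
outside every module as implicit singletons. Ties in similarity break by
lexicographic comparison of the sorted member lists, ties in `EQ` keep the
earlier (finer) level; together with sorted iteration everywhere this makes
the procedure fully deterministic — the `seed` argument only labels the
run. Edge weights are read but ignored: adjacency is binary. Defaults
`min_clique = min_complex = 10` suit study-scale networks; desk-scale
examples use 3–5.

Similarities and `EQ` terms are maintained incrementally on a dense
modularity matrix `B = A − kkᵀ/2m` (communities as indicator vectors;
overlap corrections applied only for overlapping pairs), which keeps the
agglomeration quadratic in practice at the few-hundred-node scale this
analysis operates at.

## Statistics

**Fisher.** One-sided (greater) exact test, evaluated as the hypergeometric
upper tail with both margins fixed: exact big-integer rational arithmetic
for totals ≤ 2000, `lgamma` + log-sum-exp otherwise (relative error
~1e-14). The odds ratio reported is the sample odds ratio `ad/bc` (∞ when
`bc = 0` with signal, NaN for 0/0). A zero margin flags the result
degenerate with p = 1.

**BH.** Standard step-up adjustment returned in input order. Note that BH is
*not* idempotent — re-adjusting adjusted values inflates them again through
the `m/rank` factor; the invariant that does hold, and is tested, is that
the adjusted values ordered by raw p are non-decreasing (the monotonization
step is a fixed point). Correction is applied within each test family
separately: per drug group, per module-annotation run (jointly across all
module × term pairs of one cover), per enrichment collection.

**Drug-target overrepresentation.** The counting unit is the drug. The
background is every drug with ≥ 1 human target carrying a defined action;
for each gene targeted by ≥ 1 group drug the 2×2 table is (group vs
non-group) × (targets the gene vs not). Genes targeted by no group drug are
not tested. A group drug missing from the background is an error, not a
silent drop.

**Matched permutation for eQTL sharing.** The statistic is
`|genes(A) ∩ genes(B)|` with `genes(S)` the genes regulated by ≥ 1 SNP of
`S`. Each of `n_perm` (default 10 000) replicates redraws `(A*, B*)`
uniformly from the pooled FDR-passing eQTL SNP universe with
`|A*| = |A|`, `|B*| = |B|`, `|A* ∩ B*| = |A ∩ B|` — hard constraints that
hold in every replicate by construction, not in expectation. Resampling
SNPs (not genes) preserves the many-to-many fan-out that inflates sharing
through trans hubs, which is precisely the confounder this null respects.
Sampling is pooled across studies (no per-study stratification). The
empirical p-value is `(r + 1)/(n_perm + 1)`, never zero, so a fully extreme
observation reports the floor `1/(n_perm + 1)`. SNP→gene maps are packed
into per-SNP gene bitsets, making 1e5 replicates a seconds-scale operation.

## The synthetic-data generator

`FixtureSpec` defines one study world; `gen_fixture` writes every input
table plus `config.yaml` (runnable as-is) and `manifest.json` (the planted
truth). Defaults emulate a two-disease comorbidity study at desk scale:
2000 genes, 60 planted shared genes, per-channel rates with text mining
dominant (0.70) and eQTL at 0.15, trans fan-out from a truncated geometric
distribution (mean 2, cap 8) with one high-fan-out core SNP hit by both
diseases, a 25-gene planted eQTL co-regulation excess, 240 drugs in four
groups (18/20/25/22) with 7 planted treat-A/harm-B drugs, 2 paradoxical
drugs, 3 planted overrepresented targets per group, four 12-gene clique
modules and 2% inter-module noise edges. Null-world eQTL set sizes
(150/120, intersection 2) mirror the scale of disease GWAS hit lists;
they are deliberately large enough that the null shared-gene count spreads
over many values — with small sets the tied, discrete empirical p-value is
visibly super-uniform (conservative), which is a property of the estimator,
not a sampler miscalibration.

Structural choices worth knowing when interpreting test results:

- disease-specific genes draw evidence only for their own disease, so the
  planted shared genes are *exactly* the genes associated with both
  diseases; realism enters through decoy rows (unmapped traits, boundary
  p-values and FDRs, occasional-frequency annotations, excluded terms,
  same-source duplicate reports, support-1 text entries, non-human targets,
  out-of-set edges), noise edges, and the random component of every table —
  not through cross-disease label collisions. Passing the exact-recovery
  tests therefore certifies the plumbing and the filters, not robustness to
  ambiguous gene labels;
- cross-disease drugs target only planted shared genes (anything else would
  contradict the planted shared set by construction);
- planted overrepresented targets are hit by ~80% of a group's non-cross
  drugs and no background drugs, while sporadic targets are hit by exactly
  one drug, so BH separates the two regimes cleanly;
- the generator does not emulate LD structure, per-tissue eQTL sharing,
  realistic effect sizes, or literature-bias correlations between channels.

Generation is deterministic given the spec (including its seed): two runs
produce byte-identical files, independent of Python hash randomization.

## Pipeline and problem sizes

`validate_config` fills defaults (GWAS p 1e-5, eQTL FDR 0.05, min
clique/complex 10, α 0.05, n_perm 10 000), rejects unknown keys, and
requires a seed. Outputs are TSV/GraphML/JSON with sorted iteration
everywhere; reruns are byte-identical, which the suite asserts file by
file. The run log records an (in, kept, dropped) triple for each filter
with `in = kept + dropped`. On stage failure, previously written outputs
are kept and `summary.json` is flagged incomplete.

Generated configs set `n_perm = 2000` for the bundled worlds (p floor
5e-4, ample to demonstrate the planted excess); the acceptance checks that
probe the permutation machinery directly use up to 1e5 replicates on small
universes. The default world keeps the network at 60 nodes and the drug
table at 240 drugs, sizes chosen so a full end-to-end run completes in
about a second while every statistic remains in its well-powered regime.

## Known limitations

- The exact-recovery guarantees hold for the generator's structural
  assumptions above; real extracts with noisy labels, mixed namespaces the
  alias table does not cover, or cross-source gene-set collisions will
  produce shared genes beyond any planted truth.
- The empirical permutation p is conservative under heavy ties (discrete
  statistic); report it as a bound, which is how permutation results are
  normally quoted.
- Channel co-occurrence Fisher tests are background-dependent; with the
  default universe the text-mining channel is structurally depleted in the
  synthetic worlds (both margins huge, co-occurrence capped by the shared
  set) — the eQTL channel is the one with a planted, interpretable signal.
- The module detector is exact but quadratic in community count; networks
  beyond a few thousand nodes would need a sparser similarity update than
  the dense modularity matrix used here.
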