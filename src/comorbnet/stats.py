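"""Exact tests, FDR control, overrepresentation and permutation machinery.

The one-sided Fisher exact test is evaluated from first principles as the
upper tail of the hypergeometric distribution with both margins fixed:
exact rational arithmetic for small and moderate tables, and a log-space
(``lgamma`` + log-sum-exp) tail sum for very large totals. The matched
permutation test for eQTL-set sharing resamples SNP sets that preserve the
observed set sizes *and* intersection, so the many-to-many SNP-to-gene
fan-out of the regulatory map is respected under the null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .errors import ComorbnetError

__all__ = [
    "FisherResult",
    "EnrichmentResult",
    "PermutationResult",
    "fisher_one_sided",
    "bh_adjust",
    "gene_set_overrep",
    "drug_target_overrep",
    "group_overlap_test",
    "matched_permutation",
    "sample_matched_pair",
]

# Totals up to this size use exact big-integer arithmetic; larger tables fall
# back to the log-space tail sum (relative error ~1e-14, ample for p-values).
_EXACT_TOTAL = 2000


@dataclass(frozen=True)
class FisherResult:
    """A one-sided (greater) Fisher exact test on a 2x2 table [[a, b], [c, d]]."""

    a: int
    b: int
    c: int
    d: int
    p: float
    odds_ratio: float
    side: str = "greater"
    degenerate: bool = False

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class EnrichmentResult:
    """Overrepresentation of one term: k of n query items hit a K-of-N term."""

    term: str
    k: int
    K: int
    n: int
    N: int
    p: float
    q: float
    significant: bool


@dataclass
class PermutationResult:
    """Outcome of the matched-set permutation test for shared regulated genes."""

    observed: int
    n_perm: int
    null_mean: float
    null_ge_observed: int
    p_empirical: float
    null_counts: Optional[np.ndarray] = field(default=None, repr=False)


def _validate_cells(a: int, b: int, c: int, d: int) -> None:
    for name, cell in (("a", a), ("b", b), ("c", c), ("d", d)):
        if cell < 0:
            raise ComorbnetError(f"negative cell {name}={cell} in 2x2 table")
        if cell != int(cell):
            raise ComorbnetError(f"non-integer cell {name}={cell!r} in 2x2 table")
    if a + b + c + d < 1:
        raise ComorbnetError("2x2 table total must be >= 1")


def fisher_one_sided(a: int, b: int, c: int, d: int) -> FisherResult:
    """One-sided Fisher exact test, alternative 'greater' in cell ``a``.

    Returns the exact upper-tail probability P(X >= a) of the hypergeometric
    distribution with population N = a+b+c+d, K = a+b successes and n = a+c
    draws.
    """
    _validate_cells(a, b, c, d)
    a, b, c, d = int(a), int(b), int(c), int(d)
    N = a + b + c + d
    K = a + b
    n = a + c
    hi = min(K, n)
    if N <= _EXACT_TOTAL:
        denom = math.comb(N, n)
        num = sum(math.comb(K, x) * math.comb(N - K, n - x) for x in range(a, hi + 1))
        p = float(Fraction(num, denom))
    else:
        xs = np.arange(a, hi + 1, dtype=np.float64)
        logpmf = (
            gammaln(K + 1) - gammaln(xs + 1) - gammaln(K - xs + 1)
            + gammaln(N - K + 1) - gammaln(n - xs + 1) - gammaln(N - K - n + xs + 1)
            - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
        )
        p = float(np.exp(logsumexp(logpmf))) if len(xs) else 0.0
        p = min(p, 1.0)
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    degenerate = min(K, n, N - K, N - n) == 0
    return FisherResult(a=a, b=b, c=c, d=d, p=p, odds_ratio=odds, degenerate=degenerate)


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q(i) = min_{j: p(j) >= p(i)} min(1, p(j) * m / rank(j)).
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ComorbnetError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = q_sorted
    return out.tolist()


def gene_set_overrep(
    query: set[str],
    collection: Mapping[str, Iterable[str]],
    background: set[str],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Term-by-term one-sided Fisher overrepresentation with BH correction.

    Every term of ``collection`` is intersected with ``background`` before
    testing; BH is applied across all terms of the collection.
    """
    if not background:
        raise ComorbnetError("empty background for overrepresentation test")
    extra = query - background
    if extra:
        raise ComorbnetError(
            f"query genes outside background: {sorted(extra)[:5]}"
        )
    n = len(query)
    N = len(background)
    terms = sorted(collection)
    rows = []
    for term in terms:
        members = set(collection[term]) & background
        K = len(members)
        k = len(query & members)
        res = fisher_one_sided(k, n - k, K - k, N - K - (n - k))
        rows.append((term, k, K, res.p))
    qvals = bh_adjust([r[3] for r in rows])
    results = [
        EnrichmentResult(term=t, k=k, K=K, n=n, N=N, p=p, q=q, significant=q <= alpha)
        for (t, k, K, p), q in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.q, r.p, r.term))
    return results


def group_overlap_test(
    set_x: set[str], set_y: set[str], background: set[str]
) -> FisherResult:
    """One-sided Fisher test for co-membership of two sets over a background."""
    if not background:
        raise ComorbnetError("empty background for overlap test")
    if not set_x <= background or not set_y <= background:
        raise ComorbnetError("overlap-test sets must be subsets of the background")
    a = len(set_x & set_y)
    b = len(set_x - set_y)
    c = len(set_y - set_x)
    d = len(background) - a - b - c
    return fisher_one_sided(a, b, c, d)


def drug_target_overrep(
    group,  # DrugGroup
    all_drugs,  # list[DrugRecord]
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Per-gene overrepresentation among a drug group's targets.

    The counting unit is the drug. The background is every drug with at least
    one human target carrying a defined action; for each gene targeted by at
    least one group drug the 2x2 table splits background drugs by group
    membership and by whether they target the gene. BH runs across the genes
    tested within the group.
    """
    background = [
        rec
        for rec in all_drugs
        if any(t.human and t.action_raw for t in rec.targets)
    ]
    background_ids = {rec.drug_id for rec in background}
    missing = sorted(set(group.drugs) - background_ids)
    if missing:
        raise ComorbnetError(
            "drug group contains drugs outside the human-target background: "
            + ", ".join(missing)
        )
    targets_by_drug = {
        rec.drug_id: {t.gene for t in rec.targets if t.human and t.action_raw}
        for rec in background
    }
    n = len(group.drugs)
    N = len(background)
    group_ids = set(group.drugs)
    tested: dict[str, int] = {}
    for drug_id in group_ids:
        for gene in targets_by_drug[drug_id]:
            tested[gene] = tested.get(gene, 0) + 1
    rows = []
    for gene in sorted(tested):
        a = tested[gene]
        K = sum(1 for did, genes in targets_by_drug.items() if gene in genes)
        c = K - a
        res = fisher_one_sided(a, n - a, c, N - K - (n - a))
        rows.append((gene, a, K, res.p))
    qvals = bh_adjust([r[3] for r in rows])
    results = [
        EnrichmentResult(term=g, k=a, K=K, n=n, N=N, p=p, q=q, significant=q <= alpha)
        for (g, a, K, p), q in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.q, r.p, r.term))
    return results


# --------------------------------------------------------------------------
# Matched permutation null for eQTL-set sharing


def sample_matched_pair(
    rng: np.random.Generator, universe_size: int, n_a: int, n_b: int, n_shared: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw index sets (A*, B*) with |A*| = n_a, |B*| = n_b, |A* & B*| = n_shared.

    A shared core of ``n_shared`` indices is drawn first, then disjoint
    remainders, all uniformly without replacement from ``range(universe_size)``.
    """
    total = n_a + n_b - n_shared
    if total > universe_size:
        raise ComorbnetError(
            f"cannot sample sets of sizes {n_a}, {n_b} with overlap {n_shared} "
            f"from a universe of {universe_size} SNPs"
        )
    pick = rng.choice(universe_size, size=total, replace=False)
    core = pick[:n_shared]
    rest_a = pick[n_shared : n_a]
    rest_b = pick[n_a :]
    idx_a = np.concatenate([core, rest_a])
    idx_b = np.concatenate([core, rest_b])
    return idx_a, idx_b


def _bitset_rows(links, universe: list[str]) -> tuple[np.ndarray, int]:
    """Pack the SNP-to-gene map into per-SNP gene bitsets (uint64 words)."""
    genes = sorted({l.gene for l in links})
    gidx = {g: i for i, g in enumerate(genes)}
    sidx = {s: i for i, s in enumerate(universe)}
    n_words = max(1, (len(genes) + 63) // 64)
    rows = np.zeros((len(universe), n_words), dtype=np.uint64)
    for l in links:
        g = gidx[l.gene]
        rows[sidx[l.snp_id], g >> 6] |= np.uint64(1) << np.uint64(g & 63)
    return rows, len(genes)


def _shared_gene_count(rows: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> int:
    ga = np.bitwise_or.reduce(rows[idx_a], axis=0) if len(idx_a) else np.zeros(
        rows.shape[1], dtype=np.uint64
    )
    gb = np.bitwise_or.reduce(rows[idx_b], axis=0) if len(idx_b) else np.zeros(
        rows.shape[1], dtype=np.uint64
    )
    return int(np.bitwise_count(ga & gb).sum())


def matched_permutation(
    links,
    snps_a: set[str],
    snps_b: set[str],
    n_perm: int = 10000,
    seed: int = 0,
    keep_null: bool = False,
) -> PermutationResult:
    """Empirical p-value for the number of genes co-regulated by two SNP sets.

    The observed statistic is |genes(A) & genes(B)| where genes(S) is the set
    of genes regulated by at least one SNP of S according to ``links``. Each
    of ``n_perm`` replicates redraws (A*, B*) from the pooled eQTL SNP
    universe with the sizes and intersection of the real sets held fixed, and
    recomputes the statistic. The p-value uses the (r + 1) / (n + 1)
    estimator and is therefore never zero.
    """
    if n_perm < 1:
        raise ComorbnetError("n_perm must be >= 1")
    universe = sorted({l.snp_id for l in links})
    uset = set(universe)
    if not snps_a <= uset or not snps_b <= uset:
        raise ComorbnetError("SNP sets must be subsets of the eQTL SNP universe")
    rows, _ = _bitset_rows(links, universe)
    sidx = {s: i for i, s in enumerate(universe)}
    idx_a = np.array(sorted(sidx[s] for s in snps_a), dtype=int)
    idx_b = np.array(sorted(sidx[s] for s in snps_b), dtype=int)
    observed = _shared_gene_count(rows, idx_a, idx_b)
    n_a, n_b = len(snps_a), len(snps_b)
    n_shared = len(snps_a & snps_b)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        ia, ib = sample_matched_pair(rng, len(universe), n_a, n_b, n_shared)
        # hard matching constraints hold by construction; assert cheaply
        assert len(ia) == n_a and len(ib) == n_b
        null[i] = _shared_gene_count(rows, ia, ib)
    ge = int(np.sum(null >= observed))
    return PermutationResult(
        observed=observed,
        n_perm=n_perm,
        null_mean=float(null.mean()) if n_perm else 0.0,
        null_ge_observed=ge,
        p_empirical=(ge + 1) / (n_perm + 1),
        null_counts=null if keep_null else None,
    )
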