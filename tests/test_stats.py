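"""Unit and property tests for the statistical core."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from comorbnet.errors import ComorbnetError
from comorbnet.simulate import FixtureSpec, gen_null_eqtl_pair
from comorbnet.stats import (
    bh_adjust,
    drug_target_overrep,
    fisher_one_sided,
    gene_set_overrep,
    group_overlap_test,
    matched_permutation,
    sample_matched_pair,
)
from comorbnet.drugs import DrugGroup, DrugRecord, TargetAction
from comorbnet.types import EqtlLink

from conftest import bh_oracle, hypergeom_tail_oracle


class TestFisher:
    def test_small_table_enumeration(self):
        # C(4,2) = 6 equally likely tables with both margins (2,2); only one
        # puts both successes in the first cell.
        assert fisher_one_sided(2, 0, 0, 2).p == pytest.approx(1 / 6, abs=1e-15)

    def test_zero_a_spans_whole_tail(self):
        res = fisher_one_sided(0, 5, 5, 5)
        assert res.p == pytest.approx(1.0, abs=1e-15)

    def test_matches_oracle_on_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 9, size=4)
            if a + b + c + d == 0:
                continue
            got = fisher_one_sided(a, b, c, d).p
            assert got == pytest.approx(hypergeom_tail_oracle(a, b, c, d), abs=1e-12)

    def test_matches_scipy_cross_check(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 40, size=4)
            if a + b + c + d == 0:
                continue
            ours = fisher_one_sided(a, b, c, d).p
            ref = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)

    def test_large_table_log_space_branch(self):
        # total above the exact-arithmetic cutoff exercises the lgamma path
        res = fisher_one_sided(400, 600, 300, 9000)
        ref = scipy.stats.hypergeom.sf(399, 10300, 1000, 700)
        assert res.p == pytest.approx(ref, rel=1e-9)

    def test_monotone_in_a_with_margins_fixed(self):
        # shifting mass into cell a (margins fixed) can only shrink the tail
        ps = [fisher_one_sided(a, 10 - a, 10 - a, a).p for a in range(5, 11)]
        assert all(ps[i + 1] <= ps[i] for i in range(len(ps) - 1))

    def test_negative_cell_rejected(self):
        with pytest.raises(ComorbnetError):
            fisher_one_sided(-1, 2, 3, 4)


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == [0.03]

    def test_hand_worked_stepup(self):
        # ranks 1..3: 0.01*3/1, 0.02*3/2, 0.03*3/3 -> all cummin to 0.03
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_matches_definitional_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            p = rng.uniform(size=rng.integers(1, 40)).tolist()
            assert bh_adjust(p) == pytest.approx(bh_oracle(p), abs=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(6)
        p = rng.uniform(size=100)
        ref = multipletests(p, method="fdr_bh")[1]
        assert bh_adjust(p.tolist()) == pytest.approx(ref.tolist(), abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60))
    def test_adjusted_dominates_raw_and_is_monotone(self, p):
        q = bh_adjust(p)
        assert all(qi >= pi - 1e-15 and qi <= 1.0 for qi, pi in zip(q, p))
        # the adjusted values ordered by raw p are non-decreasing, i.e. the
        # step-up monotonization is a fixed point of its own output
        order = sorted(range(len(p)), key=lambda i: p[i])
        ranked_q = [q[i] for i in order]
        assert all(
            ranked_q[i] <= ranked_q[i + 1] + 1e-15 for i in range(len(q) - 1)
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ComorbnetError):
            bh_adjust([0.5, 1.5])


class TestGeneSetOverrep:
    def test_degenerate_term_equals_background(self):
        bg = {f"g{i}" for i in range(20)}
        res = gene_set_overrep(set(list(bg)[:5]), {"all": bg}, bg)
        assert res[0].p == pytest.approx(1.0)

    def test_planted_term_matches_oracle(self):
        bg = {f"g{i}" for i in range(100)}
        term = {f"g{i}" for i in range(20)}
        query = {f"g{i}" for i in range(10)}  # all 10 inside the term
        res = gene_set_overrep(query, {"t": term}, bg)[0]
        assert res.k == 10 and res.K == 20
        assert res.p == pytest.approx(hypergeom_tail_oracle(10, 0, 10, 80), abs=1e-12)

    def test_null_calibration(self):
        # independent random query and terms: raw p <= 0.05 about 5% of the time
        rng = np.random.default_rng(9)
        bg = [f"g{i}" for i in range(200)]
        hits = total = 0
        for _ in range(200):
            query = set(rng.choice(bg, size=30, replace=False))
            term = set(rng.choice(bg, size=40, replace=False))
            res = gene_set_overrep(query, {"t": term}, set(bg))[0]
            hits += res.p <= 0.05
            total += 1
        assert 0.01 <= hits / total <= 0.12

    def test_query_outside_background_rejected(self):
        with pytest.raises(ComorbnetError):
            gene_set_overrep({"x"}, {}, {"y"})


class TestGroupOverlap:
    def test_disjoint_sets_near_one(self):
        bg = {f"d{i}" for i in range(1000)}
        x = set(list(sorted(bg))[:10])
        y = set(list(sorted(bg))[10:20])
        assert group_overlap_test(x, y, bg).p > 0.8

    def test_planted_overlap_detected(self):
        bg = {f"d{i}" for i in range(1000)}
        items = sorted(bg)
        x = set(items[:10])
        y = set(items[:8] + items[100:102])
        res = group_overlap_test(x, y, bg)
        assert res.a == 8
        assert res.p == pytest.approx(hypergeom_tail_oracle(8, 2, 2, 988), abs=1e-12)
        assert res.p < 1e-10


def _mk_drug(drug_id, genes, human=True):
    return DrugRecord(
        drug_id=drug_id,
        name=drug_id,
        targets=[TargetAction(gene=g, action_raw="inhibitor", human=human) for g in genes],
    )


class TestDrugTargetOverrep:
    def test_planted_target_matches_oracle(self):
        # 10-drug group, gene hit by 6 in-group vs 5 outside, 210-drug background
        drugs = [_mk_drug(f"D{i:03d}", ["T1"] if i < 6 else ["X"]) for i in range(10)]
        drugs += [_mk_drug(f"B{i:03d}", ["T1"] if i < 5 else ["Y"]) for i in range(200)]
        group = DrugGroup(disease="a", polarity="beneficial",
                          drugs=frozenset(f"D{i:03d}" for i in range(10)))
        res = {r.term: r for r in drug_target_overrep(group, drugs)}
        assert res["T1"].k == 6 and res["T1"].K == 11
        assert res["T1"].p == pytest.approx(
            hypergeom_tail_oracle(6, 4, 5, 195), abs=1e-12
        )

    def test_untargeted_genes_not_tested(self):
        drugs = [_mk_drug("D1", ["T1"]), _mk_drug("B1", ["T2"])]
        group = DrugGroup(disease="a", polarity="beneficial", drugs=frozenset({"D1"}))
        terms = {r.term for r in drug_target_overrep(group, drugs)}
        assert terms == {"T1"}

    def test_group_outside_background_rejected(self):
        drugs = [_mk_drug("D1", ["T1"], human=False), _mk_drug("B1", ["T2"])]
        group = DrugGroup(disease="a", polarity="beneficial", drugs=frozenset({"D1"}))
        with pytest.raises(ComorbnetError):
            drug_target_overrep(group, drugs)


def _links_one_gene_per_snp(n):
    return [
        EqtlLink(snp_id=f"rs{i}", gene=f"G{i}", study="s", tissue="t", kind="cis", fdr=0.01)
        for i in range(n)
    ]


class TestMatchedPermutation:
    def test_empty_links_give_p_one(self):
        res = matched_permutation([], set(), set(), n_perm=50, seed=1)
        assert res.observed == 0
        assert res.p_empirical == 1.0

    def test_sampler_preserves_sizes_and_overlap(self):
        rng = np.random.default_rng(4)
        for _ in range(500):
            na, nb, ns = 8, 6, 3
            ia, ib = sample_matched_pair(rng, 30, na, nb, ns)
            sa, sb = set(ia.tolist()), set(ib.tolist())
            assert len(sa) == na and len(sb) == nb and len(sa & sb) == ns

    def test_six_snp_universe_matches_enumeration(self):
        # 6 SNPs each regulating one private gene; A and B disjoint of size 2.
        # Shared genes arise only when A* and B* overlap, impossible here by
        # construction of the matched draw (|A* & B*| = 0 and fan-out 1), so
        # every null count equals observed = 0 and p = 1.
        links = _links_one_gene_per_snp(6)
        res = matched_permutation(
            links, {"rs0", "rs1"}, {"rs2", "rs3"}, n_perm=500, seed=8
        )
        assert res.observed == 0
        assert res.null_counts is None
        assert res.p_empirical == 1.0

    def test_shared_core_matches_enumeration(self):
        # one forced shared SNP: observed sharing = 1; the null preserves the
        # intersection so every replicate also shares exactly one gene -> p = 1
        links = _links_one_gene_per_snp(6)
        res = matched_permutation(
            links, {"rs0", "rs1"}, {"rs0", "rs3"}, n_perm=400, seed=8, keep_null=True
        )
        assert res.observed == 1
        assert np.all(res.null_counts == 1)
        assert res.p_empirical == 1.0

    def test_fanout_universe_matches_exhaustive_enumeration(self):
        # 6 SNPs with fan-out: compute the exact null by enumerating all
        # C(6,2) x C(4,2) ordered disjoint pairs, then compare Monte Carlo.
        import itertools

        gene_map = {
            "rs0": ["G1", "G2"],
            "rs1": ["G2", "G3"],
            "rs2": ["G3"],
            "rs3": ["G1", "G4"],
            "rs4": ["G5"],
            "rs5": ["G2", "G5"],
        }
        links = [
            EqtlLink(snp_id=s, gene=g, study="s", tissue="t", kind="trans", fdr=0.01)
            for s, genes in gene_map.items()
            for g in genes
        ]
        snps = sorted(gene_map)

        def shared(a, b):
            ga = set().union(*(gene_map[s] for s in a))
            gb = set().union(*(gene_map[s] for s in b))
            return len(ga & gb)

        observed = shared(["rs0", "rs1"], ["rs2", "rs3"])
        counts = []
        for a in itertools.combinations(snps, 2):
            rest = [s for s in snps if s not in a]
            for b in itertools.combinations(rest, 2):
                counts.append(shared(a, b))
        exact_p = sum(1 for c in counts if c >= observed) / len(counts)
        res = matched_permutation(
            links, {"rs0", "rs1"}, {"rs2", "rs3"}, n_perm=20000, seed=12
        )
        assert res.observed == observed
        assert res.p_empirical == pytest.approx(exact_p, abs=0.02)

    def test_planted_excess_hits_p_floor(self):
        # ten matched hub pairs co-regulate 3 genes each (30 shared genes in
        # total); a resampled pair would have to re-draw essentially all hub
        # SNPs on the right sides to match, so p sits at its floor
        links = []
        for i in range(10):
            for j in range(3):
                gene = f"S{3 * i + j}"
                links.append(EqtlLink(snp_id=f"rsA{i}", gene=gene, study="s",
                                      tissue="t", kind="trans", fdr=0.01))
                links.append(EqtlLink(snp_id=f"rsB{i}", gene=gene, study="s",
                                      tissue="t", kind="trans", fdr=0.01))
        for i in range(60):
            links.append(EqtlLink(snp_id=f"rs{i}", gene=f"P{i}", study="s",
                                  tissue="t", kind="cis", fdr=0.01))
        snps_a = {f"rsA{i}" for i in range(10)}
        snps_b = {f"rsB{i}" for i in range(10)}
        res = matched_permutation(links, snps_a, snps_b, n_perm=999, seed=3)
        assert res.observed == 30
        assert res.null_mean < 5
        assert res.p_empirical == pytest.approx(1 / 1000)

    def test_sets_outside_universe_rejected(self):
        links = _links_one_gene_per_snp(3)
        with pytest.raises(ComorbnetError):
            matched_permutation(links, {"rs0", "rs99"}, {"rs2"}, n_perm=10, seed=1)

    def test_infeasible_sampling_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ComorbnetError):
            sample_matched_pair(rng, 4, 3, 3, 0)


class TestNullCalibration:
    def test_pvalues_roughly_uniform_over_null_worlds(self):
        spec = FixtureSpec(seed=0)
        pvals = []
        for w in range(120):
            snps_a, snps_b, links = gen_null_eqtl_pair(spec, seed=1000 + w)
            res = matched_permutation(links, snps_a, snps_b, n_perm=99, seed=w)
            pvals.append(res.p_empirical)
        stat = scipy.stats.kstest(pvals, "uniform")
        assert stat.pvalue > 0.01
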