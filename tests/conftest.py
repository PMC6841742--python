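"""Shared fixtures: synthetic study worlds and brute-force oracles."""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import pytest

from comorbnet.pipeline import run_pipeline, validate_config
from comorbnet.simulate import FixtureSpec, gen_fixture


def hypergeom_tail_oracle(a: int, b: int, c: int, d: int) -> float:
    """Definitional upper-tail sum P(X >= a), exact rational arithmetic."""
    n_total = a + b + c + d
    row1, col1 = a + b, a + c
    denom = math.comb(n_total, col1)
    total = Fraction(0)
    for x in range(a, min(row1, col1) + 1):
        total += Fraction(math.comb(row1, x) * math.comb(n_total - row1, col1 - x), denom)
    return float(total)


def bh_oracle(pvals):
    """O(m^2) definitional BH: q(i) = min over p(j) >= p(i) of p(j)*m/rank(j)."""
    m = len(pvals)
    ranks = {}
    srt = sorted(range(m), key=lambda i: pvals[i])
    for rank, i in enumerate(srt, start=1):
        ranks[i] = rank
    out = []
    for i in range(m):
        q = min(
            min(1.0, pvals[j] * m / ranks[j])
            for j in range(m)
            if pvals[j] >= pvals[i]
        )
        out.append(q)
    return out


def brute_force_cliques(nodes, edges):
    """All maximal cliques of a small graph by subset enumeration."""
    nodes = sorted(nodes)
    adj = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    cliques = []
    for r in range(1, len(nodes) + 1):
        for combo in itertools.combinations(nodes, r):
            if all(v in adj[u] for u, v in itertools.combinations(combo, 2)):
                cliques.append(set(combo))
    maximal = [
        tuple(sorted(c))
        for c in cliques
        if not any(c < other for other in cliques)
    ]
    maximal.sort(key=lambda c: (-len(c), c))
    return maximal


@pytest.fixture(scope="session")
def demo_world(tmp_path_factory):
    """Zero-noise planted world plus its full pipeline run."""
    root = tmp_path_factory.mktemp("demo")
    spec = FixtureSpec(seed=11, noise_edge_p=0.0)
    manifest = gen_fixture(spec, root / "fixture")
    cfg = validate_config(root / "fixture" / "config.yaml")
    bundle = run_pipeline(cfg, root / "out")
    return {
        "spec": spec,
        "manifest": manifest,
        "cfg": cfg,
        "bundle": bundle,
        "fixture_dir": root / "fixture",
        "out_dir": root / "out",
    }


@pytest.fixture(scope="session")
def noisy_world(tmp_path_factory):
    """Default (noisy) planted world plus its full pipeline run."""
    root = tmp_path_factory.mktemp("noisy")
    spec = FixtureSpec(seed=7)
    manifest = gen_fixture(spec, root / "fixture")
    cfg = validate_config(root / "fixture" / "config.yaml")
    bundle = run_pipeline(cfg, root / "out")
    return {
        "spec": spec,
        "manifest": manifest,
        "cfg": cfg,
        "bundle": bundle,
        "fixture_dir": root / "fixture",
        "out_dir": root / "out",
    }
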