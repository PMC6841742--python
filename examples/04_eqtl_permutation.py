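"""Matched permutation test for shared eQTL-regulated genes.

Two diseases' GWAS-hit SNP sets co-regulate a planted block of genes through
matched trans hubs. The null redraws SNP sets of the same sizes and
intersection from the pooled eQTL SNP universe, preserving the SNP-to-gene
fan-out, so an excess of co-regulated genes is evidence of shared regulation
rather than an artifact of hub SNPs.
"""

from comorbnet import matched_permutation
from comorbnet.types import EqtlLink

links = []
# ten matched hub pairs, each co-regulating three genes (30 shared genes)
for i in range(10):
    for j in range(3):
        gene = f"SHARED{3 * i + j:02d}"
        for side in ("A", "B"):
            links.append(EqtlLink(f"rs{side}{i}", gene, "blood_meta",
                                  "whole_blood", "trans", 0.01))
# sixty background SNPs with private cis genes
for i in range(60):
    links.append(EqtlLink(f"rs{i:03d}", f"PRIV{i:03d}", "blood_meta",
                          "whole_blood", "cis", 0.02))

snps_a = {f"rsA{i}" for i in range(10)}
snps_b = {f"rsB{i}" for i in range(10)}
res = matched_permutation(links, snps_a, snps_b, n_perm=999, seed=1)

print(f"observed shared regulated genes: {res.observed}")
print(f"null mean over {res.n_perm} matched redraws: {res.null_mean:.2f}")
print(f"empirical p = (r+1)/(n+1) = {res.p_empirical:.4g}")
print("\nthe observed sharing is far above the fan-out-induced baseline, and")
print("the p-value sits at its floor 1/(n_perm+1) — the estimator never")
print("returns zero, matching how permutation bounds are reported")
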