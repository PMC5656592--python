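"""Supporting statistics: set-overlap tests, aging regression, nulls.

Reproduces the exact overlap arithmetic used when comparing a blood DEG
list against brain-region DEG lists (inputs from the published summary
table: 66 blood DEGs, an 8,708-gene common universe), then runs the
per-gene expression-on-age regression and a random gene-draw
interaction-overlap null on synthetic data.
"""

import numpy as np

import refreo as rf

# -- overlap of 66 blood DEGs with brain-region DEG lists -------------------
for region, K, k in [
    ("superior frontal gyrus", 5344, 53),
    ("primary visual cortex", 373, 9),
    ("hippocampus", 2346, 26),
    ("posterior cingulate cortex", 3273, 24),
]:
    res = rf.hypergeom_overlap(N=8708, K=K, n=66, k=k)
    print(f"{region:<28s} overlap {k:>2d}/{66}  p = {res.p:.3g}")
# p is the exact chance of seeing at least k shared genes if the 66-gene
# list were drawn at random from the 8,708-gene universe.

res = rf.hypergeom_overlap(N=8708, K=479, n=66, k=21)
print(f"{'aging-associated genes':<28s} overlap 21/66  p = {res.p:.3g}")

# direction consistency of 21 shared genes: exact binomial against 0.5
p = rf.binomial_consistency(21, 21)
print(f"21/21 consistent directions: binomial p = {p:.3g}\n")

# -- aging regression on synthetic normal samples ---------------------------
_, truth = rf.generate_purified(n_genes=1000, seed=31)
truth = rf.plant_signal(truth, n_degs=0, n_aging=50, seed=32)
normals, truth = rf.generate_mixed_cohort(
    truth, n_controls=60, n_cases=2, seed=33, age_range=(18, 56)
)
aging = rf.aging_genes(normals.controls(), alpha=0.05)
called = set(aging.index[aging["is_significant"]])
true = set(truth.aging_gene_idx)
print(f"aging genes called at FDR 0.05: {len(called)} "
      f"(recall {len(called & true) / 50:.2f} of 50 planted)")

# -- random gene-draw interaction-overlap null ------------------------------
rng = np.random.default_rng(34)
background = [f"G{i:05d}" for i in range(1000)]
partnered = set(rng.choice(background, size=250, replace=False))
partner_map = {g: ["hub"] for g in partnered}
candidates = set(rng.choice(sorted(partnered), size=30, replace=False)) \
    | set(rng.choice(background, size=10, replace=False))
res = rf.random_geneset_overlap_null(candidates, background, partner_map,
                                     B=1000, seed=35)
print(f"candidates with an interaction partner: {res.observed} observed vs "
      f"{res.null_mean:.2f} +/- {res.null_sd:.2f} expected ({res.p_label})")
# A small p says the candidate list touches the interaction network more
# often than size-matched random lists drawn from the background.
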