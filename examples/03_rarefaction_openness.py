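"""Core/pan rarefaction curves, exponential-law fits and the open/closed
pan-genome call.

For each subset size n, random strain subsets are drawn and the median
core (clusters in >=75% of the subset) and pan (clusters in any member)
sizes recorded, then fitted with f(n) = A*exp(-n/B) + C.  The pan-genome
is called open when the fitted curve still gains more than one new gene
per added genome at the full collection size.
"""

import panoeno as p

tree = p.simulate_tree(12, seed=5)
gset, truth = p.simulate_pangenome(p.SimConfig(seed=5), tree)
matches = p.score_protein_pairs(gset)
cs = p.build_clusters(matches, gset.layouts)

res = p.sample_curves(cs.presence_matrix(), n_samples=500, seed=1)
print("n, median core, median pan")
for n, c, q in zip(res.sizes, res.median_core, res.median_pan):
    print(f"{n:3d}  {c:4d}  {q:4d}")

core_fit = p.fit_exponential(res.median_core)
pan_fit = p.fit_exponential(res.median_pan)
print(f"core fit: A={core_fit.A:.1f} B={core_fit.B:.2f} C={core_fit.C:.1f}")
print(f"pan  fit: A={pan_fit.A:.1f} B={pan_fit.B:.2f} C={pan_fit.C:.1f}")
call = p.openness_call(pan_fit, N=len(res.sizes))
print(f"pan-genome is {call.status}: {call.rate_at_N:.2f} new genes per "
      f"additional genome at n={len(res.sizes)}")
# The asymptote C of the core fit estimates the final core-genome size;
# a pan slope above 1 gene/genome at full N reads as an open pan-genome.
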