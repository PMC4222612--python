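"""Define direct RBP targets from RIp-chip rankings with the predictive-value cutoff.

Genes co-purified with the RBP are ranked by IP enrichment; walking down the
list, the cumulative count of mutant-responsive genes C(k) outruns the
random baseline B(k) until the ranking stops being predictive.  That
convergence point k* cuts the list; targets found in both replicates are
kept.
"""

from rbpscreen import ripchip, simulate

ids = simulate.gene_ids(2000)
bound = frozenset(ids[:50])           # truly bound, regulated RNAs
rip, _ = simulate.gen_ripchip(2000, bound, target_shift=5.0, seed=11)

results = {}
for rep, sub in rip.groupby("replicate"):
    results[rep] = ripchip.call_targets(sub, set(bound))
    print(f"replicate {rep}: cutoff k* = {results[rep].k_star}")

final = ripchip.replicate_targets(results[1], results[2])
tp = len(final & bound)
print(f"targets in both replicates: {len(final)} "
      f"(sensitivity {tp/50:.2f}, precision {tp/len(final):.2f})")
# the cutoff lands just past the 50 planted targets in each replicate, and
# the replicate intersection removes the stragglers
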