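"""Set-overlap statistics and motif enrichment for candidate regulatory elements.

The screen's comparisons (shared targets between strains, stability vs level
changes, bound vs regulated RNAs) all reduce to hypergeometric overlap tests
with an explicit universe; candidate binding motifs are tested by
presence/absence enrichment in target vs background 3'-UTRs.
"""

from rbpscreen import overlap, simulate, validation

# two mutants de-repress overlapping ncRNA sets on the 496-ncRNA universe
universe = frozenset(f"nc{i:04d}" for i in range(496))
ids = sorted(universe)
a = overlap.GeneSet("mutant_a_up", frozenset(ids[:35]), universe)
b = overlap.GeneSet("mutant_b_up", frozenset(ids[20:38]), universe)
res = overlap.overlap_test(a, b)
print(f"overlap {res.k} of sets {res.n1}/{res.n2}; expected {res.expected} "
      f"by chance; p = {res.p_value:.2e}")

# hexamer enrichment in the 3'-UTRs of the putative targets
targets, background, _ = simulate.gen_utr_sequences(
    n_target=50, n_background=50, motif="UUAAAC", embed_rate=0.8, length=200, seed=17
)
spec = validation.MotifSpec("UUAAAC")
enr = validation.motif_enrichment(targets, background, spec)
print(f"motif present in {enr['target_rate']:.0%} of targets vs "
      f"{enr['background_rate']:.0%} of background; p = {enr['p_value']:.2e}")

# the reporter construct used for functional validation carries 8 tandem copies
construct = "UUAAAC" * 8
print(f"reporter: {validation.count_motif(construct, spec)} copies of UUAAAC, "
      f"{validation.count_motif(construct, validation.MotifSpec('GUAAAC'))} of the mutated GUAAAC")
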