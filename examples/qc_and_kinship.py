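"""Variant QC cascade and relatedness pruning on a simulated duo.

Applies the depth/quality/missingness site filters, reports Ti/Tv, then
detects a planted parent-offspring pair with the KING-robust kinship
estimator and prunes one member.
"""

from popmosaic import qc
from popmosaic import simdata as sim

freqs = sim.sample_source_frequencies(60_000, [0.1], seed=1)
g = sim.simulate_duo(freqs, n_unrelated=4, seed=2)

phi = qc.king_kinship(g, "PARENT", "OFFSPRING")
print(f"KING-robust kinship of the planted duo: {phi:.3f} "
      "(first-degree expectation 0.25)")
phi_u = qc.king_kinship(g, "U0", "U1")
print(f"KING-robust kinship of an unrelated pair: {phi_u:.3f} (expect ~0)")

pruned, removed = qc.prune_relatives(g, threshold=0.177)
print(f"pruning at the first/second-degree boundary removed: {removed}")

# depth/quality filters need per-genotype metadata; simulate with depth
specs = [sim.AdmixtureSpec("P", [1.0], 10)]
g2 = sim.simulate_admixed_genotypes(freqs, specs, seed=3, with_depth=True)
filtered, report = qc.filter_sites(g2)
print(f"site filters: {report.input_sites} sites in, "
      f"{report.surviving_sites} out, removals by rule: {report.removed}")
print(f"Ti/Tv of survivors: {report.ti_tv:.2f} "
      "(alleles here are simulated uniformly, so ~0.5; real exomes run ~2.5+)")
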