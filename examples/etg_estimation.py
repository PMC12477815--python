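"""Estimate per-individual NMD efficiency from endogenous target genes (ETG).

Simulates a cohort in which each sample degrades its NMD-target transcripts
by a known factor exp(-eta), runs the filtering cascade and the negative-
binomial regression, and compares the sign-flipped coefficient (iNMDeff)
with the simulated truth.
"""

import numpy as np

from nmdeff import CohortSpec, estimate_inmdeff_etg, filter_etg_pairs, simulate_etg_counts

spec = CohortSpec(n_individuals=12, base_eta=1.0, individual_effect_sd=0.4,
                  theta=10.0, depth=100.0, seed=5)
sim = simulate_etg_counts(spec, n_pairs=40)

print(f"{'sample':<10}{'true eta':>9}{'iNMDeff':>9}{'SE':>7}{'pairs':>7}")
errs = []
for ind in sim.counts.columns:
    rows = filter_etg_pairs(sim.pairs, sim.counts, ind,
                            transcript_lengths=sim.transcript_lengths)
    est = estimate_inmdeff_etg(ind, "all", rows)
    truth = sim.manifest.eta[ind]
    errs.append(abs(est.inmdeff - truth))
    print(f"{ind:<10}{truth:>9.3f}{est.inmdeff:>9.3f}{est.standard_error:>7.3f}"
          f"{est.n_units:>7}")

print(f"\nmean |error| = {np.mean(errs):.3f}")
print("iNMDeff is the negative natural-log target/control expression ratio: "
      "a value of 1 means NMD-target transcripts are degraded to exp(-1) "
      "~ 37% of their paired controls; higher = more efficient decay.")
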