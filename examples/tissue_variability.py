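"""Tissue-level randomization tests on iNMDeff estimates.

Builds a multi-tissue cohort in which two tissues have shifted NMD
efficiency, then runs the inter-tissue variability deviation test (ITNVD)
and the per-tissue deviation test (TND), and shows the empirical-FDR
bookkeeping used to calibrate replicated association counts.
"""

import numpy as np

from nmdeff import CohortSpec, empirical_fdr, itnvd_test, tnd_test

spec = CohortSpec(
    tissues=[("brain", 80, -0.4), ("testis", 80, -0.25)]
    + [(f"tissue_{i}", 80, 0.0) for i in range(8)],
    base_eta=1.0, individual_effect_sd=0.3, seed=9,
)
frame = spec.sample_frame()
values, tissues = frame["eta"].to_numpy(), frame["tissue"].to_numpy()

res = itnvd_test(values, tissues, n_iter=2000, seed=1)
print(f"ITNVD = {res.deviation:.3f} (observed SD of tissue medians "
      f"{res.observed:.3f} vs null median {res.null_median:.3f}), "
      f"p = {res.p_value:.2g}")

print(f"\n{'tissue':<12}{'TND':>8}{'p':>10}")
for t in sorted(set(tissues)):
    r = tnd_test(values, tissues, t, n_iter=2000, seed=1)
    print(f"{t:<12}{r.deviation:>8.3f}{r.p_value:>10.2g}")

print("\nPositive TND: the tissue is more NMD-efficient than chance; the "
      "two planted low-efficiency tissues show negative TND at the "
      "permutation floor p = 1/2000 = 5e-4.")

fdr = empirical_fdr(observed_hits=10, observed_tests=10_000,
                    randomized_hits=3, randomized_tests=10_000)
print(f"\nempirical FDR for 10 observed vs 3 randomized replicated hits: "
      f"{100 * fdr:.0f}%")
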