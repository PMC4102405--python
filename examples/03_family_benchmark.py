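"""Leave-one-family-out parameter recovery on synthetic homologous families.

Generates 12 families of 4 members with known Gibbs-Helmholtz curves,
observes each member's folding free energy at three temperatures with
0.5 kcal/mol Gaussian noise, runs the full family-context prediction
pipeline (0 K anchor, amplitude factor k, temperature factor omega -- all
computed without the target's own experimental values) and summarises how
well the melting temperatures are recovered.
"""

import warnings

import numpy as np

from thermocurve import performance_stats, synthetic_family_benchmark

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    df = synthetic_family_benchmark(n_families=12, n_members=4,
                                    noise_sd=0.5, seed=0)

ok = df[~df.no_melting]
err = (ok.tm_pred - ok.tm_true).abs()
stats = performance_stats(list(zip(ok.tm_pred, ok.tm_true)), quantity="tm")
print(f"{len(df)} members predicted, {len(ok)} with a usable melting "
      f"transition, {int(df.anchor_used.sum())} required the 0 K anchor")
print(f"median |Tm error| = {err.median():.2f} C, "
      f"sigma = {stats.sigma:.2f} C, Pearson r = {stats.r:.3f}")
print(df.head(4)[["id", "tm_true", "tm_pred", "dcp_true", "dcp_pred",
                  "k", "omega"]].to_string(index=False))
print("\nEach member's curve corrections were calibrated only on its "
      "family siblings, so these numbers are honest cross-validated "
      "recovery errors, not fits.")
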