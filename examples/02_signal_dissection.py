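"""Dissecting a locus with two causal variants into distinct signals.

Simulates one locus harbouring two causal variants in low LD, then runs the
iterative approximate conditional analysis: starting from the lead, each
round conditions every variant's Z-score on the current set via the
ancestry-matched LD references and appends the strongest residual
association while it stays locus-wide significant (p < 1e-5).  Index
variants are then assigned by leave-one-out conditioning.
"""

import numpy as np

from transgwas import meta, pipeline, signals, simulate

cfg = simulate.SimConfig(seed=33, n_loci=1, causal_per_locus=2, n_null_variants=500)
panel = simulate.simulate_panel(cfg)
truth = panel.loci[0]

result, log = meta.meta_analyse(panel.studies)
(locus,) = meta.define_loci(result)
data = pipeline.build_locus_data(panel.studies, locus, panel.ld_for(locus))
lead = int(np.flatnonzero(data.variants["pos"] == locus.lead_pos)[0])

sset = signals.dissect_locus(data, lead, lambda_gc=log["lambda_meta"])
sset = signals.index_variants(data, sset, lambda_gc=log["lambda_meta"])

print("planted causal positions:",
      truth.variants["pos"].to_numpy()[truth.causal_idx].tolist())
print(f"distinct signals found: {sset.n_signals}")
for s in sset.signals:
    pos = int(data.variants["pos"].iloc[s.index])
    print(f"  {s.signal_id}: index variant at {pos}, "
          f"conditional p = {s.p_cond[s.index]:.3e}")
print()
print("Each signal's index is the variant with the strongest residual")
print("association after conditioning on the other signals at the locus.")
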