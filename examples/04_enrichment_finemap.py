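"""Annotation enrichment and annotation-informed fine-mapping, end to end.

Simulates a 20-locus panel in which causal variants fall in a cell-type
annotation with four-fold enrichment, runs the whole pipeline, and shows the
joint log-fold-enrichment estimate and the credible sets it sharpens.
"""

import numpy as np

from transgwas import pipeline, simulate

cfg = simulate.SimConfig(seed=12, n_loci=20)
panel = simulate.simulate_panel(cfg, causal_counts=[1 if i % 2 == 0 else 2
                                                    for i in range(20)])
res = pipeline.analyse_panel(panel.studies, panel.ld_for, panel.tracks,
                             forward_selection=False)

print(f"loci found: {len(res.loci)} / {cfg.n_loci} planted")
print(f"distinct signals: {res.n_signals}")

model = res.enrichment_model
print("\njoint enrichment model:")
print(model.as_frame().to_string(index=False))
print(f"(planted fold enrichment: 4.0)")

sizes = [r.credible_set_size for r in res.finemap_results]
n_hc = sum(r.high_confidence is not None for r in res.finemap_results)
print(f"\n99% credible sets: median size {int(np.median(sizes))}, "
      f"max {max(sizes)}")
print(f"high-confidence signals (one variant with pi > 0.5): "
      f"{n_hc} / {len(res.finemap_results)}")
for r in res.finemap_results[:3]:
    idx, pi = r.high_confidence if r.high_confidence else (None, float("nan"))
    print(f"  {r.signal_id}: credible set size {r.credible_set_size}, "
          f"top posterior pi = {pi:.3f}")
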