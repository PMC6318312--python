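"""Two-sample MR of a trait on an outcome with pleiotropic outlier exclusion.

Simulates 94 instruments (lead variants at trait loci) with a planted causal
effect of -0.3 and a 10% pleiotropic outlier fraction, harmonises exposure
and outcome (dropping palindromic variants), screens instruments with
modified (radial) Q-statistics, and compares the three estimators.
"""

import numpy as np

from transgwas import mr, simulate

cfg = simulate.SimConfig(
    seed=17,
    mr=simulate.MRConfig(pleiotropy_fraction=0.1, pleiotropy_scale=0.5),
)
exposure, outcome, truth = simulate.simulate_mr(cfg)

instr = mr.harmonize(exposure, outcome)
print(f"instruments: {cfg.mr.n_instruments} simulated, "
      f"{len(instr)} after palindrome exclusion")

retained, outliers, qj = mr.modified_q_filter(instr)
found = set(zip(outliers["chrom"], outliers["pos"]))
print(f"modified-Q outliers removed: {len(outliers)} "
      f"(planted pleiotropic: {len(truth['outlier_pos'])}, "
      f"detected: {len(truth['outlier_pos'] & found)})")

rng = np.random.default_rng(17)
for fit in (
    mr.ivw(retained, outcome="outcome"),
    mr.weighted_median(retained, outcome="outcome", rng=rng),
    mr.mr_egger(retained, outcome="outcome"),
):
    line = (f"  {fit.method:>15}: estimate {fit.estimate:+.3f} "
            f"(se {fit.se:.3f}, p {fit.p:.2e})")
    if fit.egger_intercept:
        i0, i_se, i_p = fit.egger_intercept
        line += f"; intercept {i0:+.4f} (p {i_p:.2f})"
    print(line)
print(f"\nplanted causal effect: {truth['causal_effect']}")
print("The Egger intercept near zero indicates no directional pleiotropy")
print("among the retained instruments.")
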