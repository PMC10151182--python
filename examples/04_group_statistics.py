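"""Control-versus-patient group statistics on a synthetic cohort.

Controls carry planted hexadirectional theta modulation; patients have
grid_gain = 0.  The study computes, per participant, the cross-validated
modulation coefficient beta and the aligned-versus-misaligned theta power
difference, and compares groups with pooled-variance t-tests and Hedges' g.
"""

from gridtheta import studies

out = studies.cohort_pattern_study(n_controls=6, n_patients=5,
                                   duration=240.0, seed=1)

cb, pb, gc = out["control_beta"], out["patient_beta"], out["group_comparison"]
print(f"controls : beta = {cb.mean:+.3f} Z, t({cb.df:.0f}) = {cb.statistic:.2f}, "
      f"p = {cb.p:.2g}")
print(f"patients : beta = {pb.mean:+.3f} Z, t({pb.df:.0f}) = {pb.statistic:.2f}, "
      f"p = {pb.p:.2g}")
print(f"group difference: t({gc.df:.0f}) = {gc.statistic:.2f}, p = {gc.p:.2g}, "
      f"Hedges' g = {gc.g:.2f}")
ad = out["aligned_diff"]
print(f"aligned - misaligned power (controls): {ad.mean:+.3f} Z, p = {ad.p:.2g}")
print(f"aligned sample fraction (controls)   : {out['aligned_fraction_mean']:.3f} "
      "(geometry predicts 0.5)")
sig = [(c['symmetry'], c['band']) for c in out['table'] if c['significant']]
print(f"significant (symmetry, band) cells, Bonferroni over 25: {sig}")
print("\nOnly the 6-fold theta cell should be significant in controls, and no"
      "\ncell in patients - the planted group dissociation.")
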