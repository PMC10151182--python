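"""Recover a planted grid orientation with the quadrature filter.

Simulates one participant whose theta envelope is modulated as
cos(6(theta - phi)) around a planted orientation phi, then runs the full
analysis path: zero-phase filtering, movement-onset epoching, Hilbert theta
power, alternate-epoch fold split, quadrature-filter orientation estimate
on one fold and cosine regression on the other.
"""

import numpy as np

from gridtheta import circstat, synthcohort as sc
from gridtheta.pipeline import AnalysisParams, grid_fit

PHI, GAIN = 23.0, 0.5

traj = sc.simulate_trajectory(sc.ArenaSpec(), sc.KinematicsSpec(), 180.0, 7)
osc = sc.OscillatorSpec(n_voxels=1, grid_voxel_index=0,
                        grid_gain=GAIN, grid_orientation=PHI)
vox = sc.simulate_voxel_series(traj, osc, 8)

gf = grid_fit(traj, {str(traj.block_id[0]): vox}, AnalysisParams(do_spectra=False))
phis = [f.orientation_deg for f in gf.fits]
phi_hat = circstat.circ_mean_nfold(phis, 6).value

print(f"planted orientation : {PHI:.2f} deg (modulo 60)")
print(f"recovered orientation: {phi_hat:.2f} deg  "
      f"(per fold: {', '.join(f'{p:.2f}' for p in phis)})")
print(f"planted gain         : {GAIN:.3f}")
print(f"recovered beta       : {gf.beta_raw[0]:.3f} (envelope units), "
      f"{gf.beta[0]:.3f} (Z units)")
print("\nThe fold-reversed cross-validation estimates the orientation on one"
      "\nhalf of the movement epochs and the modulation depth on the other,"
      "\nso a null signal gives beta centred on zero.")
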