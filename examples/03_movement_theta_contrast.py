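"""Movement-onset versus stationary theta power.

The generator raises the theta amplitude starting 0.5 s before each
movement bout.  Morlet spectrograms (five cycles, 40 log-spaced bins,
2-70 Hz) of movement-onset epochs are normalized by the per-time sum across
frequencies, log-transformed and baseline corrected by stationary-period
power; the scalar contrast averages the 4-10 Hz bins.
"""

from gridtheta import studies

out = studies.spectral_contrast_study(n_participants=4, duration=240.0, seed=0)

print(f"theta contrast (movement [-0.5, 0.5] s vs stationary [0, 1] s): "
      f"{out['theta_contrast_mean']:+.4f}")
print(f"pre-onset theta contrast [-0.5, 0) s : {out['preonset_mean']:+.4f}")
print(f"early-window contrast [-2.5, -1] s   : {out['early_window_mean']:+.4f}")
print("\nPositive contrast before t = 0 shows the theta rise leading movement"
      "\nonset, as planted; the early window (long before onset) stays near"
      "\nbaseline.")
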