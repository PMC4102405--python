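# Full default configuration for the thermocurve pipeline.
# Values marked [published] are the method's published operating points;
# values marked [package default] fill gaps the method description leaves
# open and can be overridden here without code changes.

tm_cutoff_c: 70.0        # [package default] meso/thermo split temperature (C)
identity_cap_pct: 25.0   # [published] max pairwise sequence identity per set
sigma_distance: 10.0     # [published] sparse-data correction, distance potentials
sigma_torsion: 20.0      # [published] sparse-data correction, torsion potentials
smoothing_kernel:        # [package default] decreasing half-kernel
  - 1.0                  #   center bin
  - 0.5                  #   +-1 neighbour
  - 0.25                 #   +-2 neighbour (symmetrised, normalised in code)
min_separation: 2        # [package default] minimum |i-j| for distance pairs
exclude_fraction: 0.1    # [published] worst-prediction exclusion in statistics
anchor_policy: one_pass  # single corrective re-fit with the 0 K anchor
seed: 0
# [package default] rectangular Ramachandran partition; rows are
# (label, phi_lo, phi_hi, psi_lo, psi_hi), first match wins, catch-all "O".
torsion_domain_table:
  - [A, -110.0, -40.0, -80.0, -5.0]
  - [C, -180.0, -40.0, -5.0, 60.0]
  - [B, -180.0, -90.0, 90.0, 180.0]
  - [P, -90.0, -40.0, 90.0, 180.0]
  - [G, 30.0, 110.0, -20.0, 80.0]
  - [E, 30.0, 180.0, 130.0, 180.0]
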