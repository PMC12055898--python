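# Baseline tissue parameters for the three-tissue cortical bone composite.
# Units: mm-N-MPa system (E in MPa, Gc in N/mm).  Poisson's ratio 0.3 for all
# tissue classes.  These are the centre points of both designs of experiments.

[matrix]
E = 15000.0
nu = 0.3
Gc = 0.35

[osteon]
E = 13500.0
nu = 0.3
Gc = 0.5

[cement_line]
E = 15000.0
nu = 0.3
Gc = 0.1

[phase_field]
ell = 0.0025
k_res = 1e-7
damage_threshold_for_crack = 0.01
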