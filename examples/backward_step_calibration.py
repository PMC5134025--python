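"""Backward-facing-step configuration and the kinetics time-scale map.

The steady backward-facing step is the calibration geometry for the
accelerated kinetics: with the coagulant diffusivity augmented by a
factor 150, about 40 s of simulated growth corresponds to roughly
90 min of real thrombus formation (simulated time × augmentation
factor).  This demo runs a short (4 s) segment and shows the coagulant
accumulating in the recirculation bubble behind the step — where the
thrombus later forms — while the high-shear channel keeps it cleared.
"""

import numpy as np

from thromboflow.cases import bfs_thrombosis_case
from thromboflow.coupler import run_case, time_scale_estimate

cfg = bfs_thrombosis_case(sim_time=4.0)
print(f"augmentation factor f_aug = {cfg.thrombosis.f_aug:.0f}")
print(f"calibration run length    = 40 s  ->  equivalent real time "
      f"{time_scale_estimate(40.0, cfg.thrombosis.f_aug):.0f} s (~100 min)\n")

res = run_case(cfg)
g = res.grid
rec = g.regions["step_recirculation"]
up = g.x_centers[:, None] * np.ones((1, g.ny)) < cfg.geometry.upstream_len
C = res.state.C
print(f"after {res.state.t:.1f} s of simulated time:")
print(f"  max coagulant in recirculation zone : {C[rec].max():9.1f} nmol/l")
print(f"  max coagulant upstream of the step  : {C[up & g.mask].max():9.1f} nmol/l")
print(f"  max bound platelets (clot marker)   : {res.state.BP.max():9.2f} nmol/l")
print("\nThe coagulant piles up in the low-shear bubble behind the step, with")
print("upstream levels ~100x lower (a diffusion tail near the lip that the")
print("high-shear consumption keeps in check). Run longer (sim_time ~ 8-40 s)")
print("and BP in the bubble crosses the clot threshold BP_t = 20 nmol/l while")
print("the channel stays clean of clot.")
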