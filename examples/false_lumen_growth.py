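"""False-lumen thrombosis in an idealized dissection (coarse, quick demo).

A true lumen (open both ends) and a false lumen (closed both ends) share
a solid flap pierced by one proximal tear.  After a two-cycle flow
spin-up, the thrombosis model runs for six cardiac cycles: coagulant is
released at false-lumen walls (TAWSS < 0.2 Pa), platelets bind where
averaged shear stays below 50 1/s, and the growing clot throttles the
tear exchange.  The full study protocol uses a finer grid and more
cycles (see thromboflow.cases.dissection_s1_case defaults).
"""

import numpy as np

from thromboflow.cases import dissection_s1_case
from thromboflow.coupler import growth_report, run_case

cfg = dissection_s1_case(n_cycles=6, resolution=2e-3)
res = run_case(cfg)

df = growth_report(res)
cols = ["cycle", "phase", "max_BP", "thrombosed_frac", "max_RT_cycles", "fl_influx"]
print(df[cols].to_string(index=False, float_format=lambda x: f"{x:.3g}"))

g = res.grid
p = cfg.thrombosis
th = (res.state.BP > p.BP_t) & g.mask
fl = g.regions["false_lumen"]
tl = g.regions["true_lumen"]
print(f"\nthrombosed cells: {th.sum()}  (false lumen: {(th & fl).sum()}, "
      f"true lumen: {(th & tl).sum()})")
print(f"max residence time in the false lumen: "
      f"{res.state.RT[fl].max() / cfg.waveform.T:.1f} cycles")
print("\nReading the table: max_BP grows ~4 nmol/l per cycle inside the gated")
print("false lumen; thrombosed_frac is the FL area above the clot threshold")
print("BP_t = 20 nmol/l; fl_influx (m^2/s) is the cycle-mean exchange through")
print("the tear, which falls as the clot blocks it.")
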