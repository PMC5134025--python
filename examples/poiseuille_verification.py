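"""Solver verification: steady and pulsatile channel flow vs closed forms.

Runs the Newtonian channel benchmarks and prints the discretization
errors against the exact Poiseuille parabola and the oscillatory
Stokes-layer (Womersley) series.
"""

from thromboflow.cases import poiseuille_benchmark, womersley_benchmark

b = poiseuille_benchmark(ny=64)
print("Steady Poiseuille channel (ny = 64):")
print(f"  velocity-profile L2 error : {b['profile_l2']:.2e}  (tolerance 5e-3)")
print(f"  centreline error          : {b['centerline']:.2e}")
print(f"  wall-shear-stress error   : {b['wss']:.2e}  (tolerance 1e-2)")
print(f"  net mass residual         : {b['mass_residual']:.2e}  (projection is exact)")

w = womersley_benchmark(alpha=5.0, ny=64)
print(f"\nPulsatile channel, Womersley number alpha = {w['alpha']:.0f}:")
print(f"  last-cycle velocity L2 error: {w['l2']:.2e}  (tolerance 2e-2)")
print("\nBoth flows are exact solutions of the solved equations, so the")
print("errors above are pure discretization error of the staggered-grid scheme.")
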