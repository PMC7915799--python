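"""Split a breathing flow between two nasal passages and compute the
aerodynamic drag coefficient.

The right passage is narrowed to 70% of the left diameter; in laminar
flow the d^4 law sends most of the flow through the wider side.
"""

from sinudens import aerodynamics as aero

left = aero.circular_tube(0.008, 0.1)    # 8 mm passage
right = aero.circular_tube(0.0056, 0.1)  # narrowed passage
res = aero.split_flow(left, right, q_total=0.3e-3)  # 0.3 L/s quiet breathing

print(f"flow left  : {res.q1 * 1000:.3f} L/s")
print(f"flow right : {res.q2 * 1000:.3f} L/s")
print(f"pressure drop : {res.dp_pa:.2f} Pa")
print(f"drag A = dp/Q : {res.drag_total_kpa_per_lps:.4f} kPa/(L/s)")
print("regimes:", {k: v[0]["regime"] for k, v in res.diagnostics.items()})
# The drag coefficient A is indicator x5; obstruction raises it, which
# is what rhinomanometry measures directly as dp/Q.
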