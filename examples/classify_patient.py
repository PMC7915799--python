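"""Assign a new patient's indicator vector to the nearest diagnostic
cluster.

The example vector (fluid at 36 Hu, nearly blocked ostium, moderate
mucosal thickening, half-filled sinus, raised nasal drag) resembles the
acute purulent cohort.
"""

from sinudens import discriminant as dm

patient = {"x1": 36.0, "x2": 22.0, "x3": 25.0, "x4": 50.0, "x5": 2.1}
clusters = dm.load_group_stats()
res = dm.classify_patient(patient, clusters)

print("ranked normalized Euclidean distances to cluster centres:")
for group, dist in res.ranking:
    print(f"  {group:20s} {dist if dist != float('inf') else 'excluded (zero-spread feature mismatch)'}")
print(f"\nmost probable form: {res.winner}")
print("compliance weights:", {k: round(v, 3) for k, v in res.weights.items()})
# The shortest distance names the most probable form; the weights rank
# the remaining candidates (softmax over negative squared distances).
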