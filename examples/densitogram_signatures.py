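"""Cast a radial densitogram fan over lesion phantoms and classify them.

For each phantom preset, profiles are sampled from the sinus centre
along the lower hemisphere and their shape signatures aggregated into a
sinus-level finding.
"""

from sinudens import densitogram as dg
from sinudens import phantom

for preset in ("conditional_norm", "serous_40", "cyst", "perforation", "foreign_body"):
    vol, labels, _ = phantom.make_sinus_phantom(phantom.preset_config(preset))
    k = vol.n_slices // 2
    center = dg.sinus_center(labels, k)
    radius = (12.0 + 2.5) / vol.spacing_mm[1] + 3  # reach through the bone wall
    fan = dg.radial_fan(center, radius, n_rays=13, slice_index=k,
                        slice_shape=labels.shape[1:])
    sigs = [dg.classify_profile(dg.sample_profile(vol, t)) for t in fan]
    label, support, counts = dg.aggregate_signatures(sigs)
    print(f"{preset:17s} -> {label.value:14s} ({support}/13 rays; {counts})")
# A normal cavity shows an air plateau ending in a bone peak on every
# ray; each lesion preset flips the rays that cross it to its signature,
# and the priority rule promotes the most specific evidence.
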