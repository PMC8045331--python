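"""Measure a directional margin on an analytic slab phantom.

Builds a 10 mm slab GTV whose CTV extends 7 mm beyond it on the anatomical
left and 2 mm on the right, then casts expansion vectors in both directions.
Because the faces are flat and perpendicular to the probes, every accepted
vector has the same length and the median recovers the applied offsets
exactly.
"""

from ctvmargins import DirectionSpec, directional_margin, example_specs, make_phantom

phantom = make_phantom(example_specs()["asymmetric_slab"])

for label in ("L", "R"):
    direction = DirectionSpec.from_label(label)
    result = directional_margin(phantom.gtv, phantom.ctv, direction)
    counters = result.vector_set.counters()
    print(
        f"direction {label}: M = {result.margin_mm:.1f} mm "
        f"({result.n_used} vectors, {counters['n_rejected_interior']} interior "
        f"rejections, truth {phantom.truth[label]:.1f} mm)"
    )

# M is the median expansion-vector length from the GTV surface to the CTV
# surface parallel to the probe; L/R probe the 7 mm and 2 mm faces.
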