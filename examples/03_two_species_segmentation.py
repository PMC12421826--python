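"""Segment a two-species capacitance frame and compare the populations.

Two colonies with different dielectric deficits share the field of view;
blur + Otsu + morphology recovers the boundary, and the per-region
histograms quantify how separable the species are (overlap coefficient
OVL: 1 = identical, 0 = disjoint).
"""

import numpy as np

from ecitools import (
    DielectricParams,
    SensorGeometry,
    SpeciesTexture,
    forward_capacitance,
    make_two_species_phantom,
    region_histograms,
    segment_species,
    two_species_dielectric,
)

geometry = SensorGeometry(n_rows=128, n_cols=256)
species_a = SpeciesTexture(delta_c_fF=40.0)
species_b = SpeciesTexture(delta_c_fF=47.0)

phantom = make_two_species_phantom(geometry, species_a, species_b, boundary_seed=3)
params = two_species_dielectric(species_a, species_b, DielectricParams(noise_sd_fF=1.0))
frame = forward_capacitance(phantom, params, geometry, seed=103)

labels = segment_species(frame)
hist = region_histograms(frame, labels)

assigned = labels.labels > 0
accuracy = max(
    np.mean((labels.labels == phantom.species)[assigned]),
    np.mean((labels.labels == (3 - phantom.species))[assigned]),
)
print(f"classes: {labels.classes} (degenerate: {labels.degenerate})")
print(f"areas (px): {[labels.area(i) for i in (1, 2)]}, boundary band: {labels.area(0)}")
print(f"pixel accuracy vs ground truth (outside the boundary band): {accuracy:.4f}")
print(f"histogram overlap coefficient: OVL = {hist.overlap:.3f}")
# A low OVL confirms the two populations occupy distinct capacitance
# ranges, so they can be told apart by their electrical signature alone.
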