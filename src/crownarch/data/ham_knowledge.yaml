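# Hallé architecture model (HAM) knowledge base.
#
# Expert inputs, not fitted constants: the prototype centres on the
# (P4, P7) feature pair encode the qualitative low / moderate / high
# positions of the four models (P4 = largest 1 m super-voxel point
# fraction, P7 = stem-space voxel occupancy).  Edit freely for other
# feature pairs or stands.
#
# Two species->model readings circulate for the four boreal species and
# they disagree; both are recorded here (species_links) without silent
# reconciliation.  `narrative` ties each species to the model named in the
# classification workflow; `habit_table` pairs each species directly with
# a growth-habit row, which matches a *different* model for every species.

feature_pair: [P4, P7]

models:
  Massart:
    trunk: "monopodial, indeterminate"
    branches: "plagiotropic, (main branches) produced in whorls"
    growth: "rhythmic"
    center: {P4: 0.10, P7: 0.03}
    quadrant: [low, low]
  Rauh:
    trunk: "monopodial"
    branches: "orthotropic, morphogenetically equivalent to the trunk"
    growth: "rhythmic"
    center: {P4: 0.23, P7: 0.03}
    quadrant: [high, low]
  Roux:
    trunk: "monopodial, indeterminate"
    branches: "plagiotropic, monopodial, non-phyllomorphic"
    growth: "continuous"
    center: {P4: 0.17, P7: 0.03}
    quadrant: [low, high]
  Attim:
    trunk: "monopodial"
    branches: "orthotropic, morphogenetically equivalent to the trunk"
    growth: "more or less continuous"
    center: {P4: 0.10, P7: 0.09}
    quadrant: [high, high]

# quadrant rule: (low/high on axis 1, low/high on axis 2) -> model.
# Three of the four models sit at low P7, which four quadrants cannot
# express -- this default map is only meaningful for feature pairs with a
# genuine 2x2 layout; nearest_center is the default rule.
quadrant_map:
  low,low: Massart
  high,low: Rauh
  low,high: Roux
  high,high: Attim

species_links:
  narrative: {PA: Massart, PS: Rauh, PT: Roux, QR: Attim}
  habit_table: {PS: Massart, PT: Rauh, QR: Roux, PA: Attim}
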