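# Curated fatty-acid reaction model used for pathway-distance calculation.
#
# Biosynthesis graph: de novo synthesis (C2 elongation steps up to C26:0)
# with the initial SCD-dependent desaturations to C16:1/C18:1 and the
# elongation series of the resulting monounsaturates, plus the omega-3 and
# omega-6 polyunsaturated pathways (Delta-6/Delta-5 desaturations, ELOVL
# elongations, and the final peroxisomal C2-removal steps producing C22:5 and
# C22:6).  Double-bond positions are deliberately omitted: species with equal
# carbon and double-bond counts from different pathways (C18:3, C20:4, C22:5,
# C24:5) are isobaric under brutto annotation and merged into single nodes,
# recorded by their combined tags.  The Delta-12/Delta-15 desaturations
# (C18:1 -> C18:2 -> C18:3) are absent in humans, so the polyunsaturated
# component is deliberately disconnected from the de novo series.
#
# Beta-oxidation graph (acyl-carnitine domain): linear chains of C2
# degradation steps (C18 -> C16 -> ... -> C2) per double-bond count.
#
# Edit or replace this file to substitute a different curated reaction set.

biosynthesis:
  fatty_acids:
    - {carbons: 2,  double_bonds: 0, tags: [de-novo]}
    - {carbons: 4,  double_bonds: 0, tags: [de-novo]}
    - {carbons: 6,  double_bonds: 0, tags: [de-novo]}
    - {carbons: 8,  double_bonds: 0, tags: [de-novo]}
    - {carbons: 10, double_bonds: 0, tags: [de-novo]}
    - {carbons: 12, double_bonds: 0, tags: [de-novo]}
    - {carbons: 14, double_bonds: 0, tags: [de-novo]}
    - {carbons: 16, double_bonds: 0, tags: [de-novo]}
    - {carbons: 18, double_bonds: 0, tags: [de-novo]}
    - {carbons: 20, double_bonds: 0, tags: [de-novo]}
    - {carbons: 22, double_bonds: 0, tags: [de-novo]}
    - {carbons: 24, double_bonds: 0, tags: [de-novo]}
    - {carbons: 26, double_bonds: 0, tags: [de-novo]}
    - {carbons: 16, double_bonds: 1, tags: [de-novo]}
    - {carbons: 18, double_bonds: 1, tags: [de-novo]}
    - {carbons: 20, double_bonds: 1, tags: [de-novo]}
    - {carbons: 22, double_bonds: 1, tags: [de-novo]}
    - {carbons: 24, double_bonds: 1, tags: [de-novo]}
    - {carbons: 18, double_bonds: 2, tags: [omega-6]}
    - {carbons: 18, double_bonds: 3, tags: [omega-6]}
    - {carbons: 18, double_bonds: 3, tags: [omega-3]}
    - {carbons: 18, double_bonds: 4, tags: [omega-3]}
    - {carbons: 20, double_bonds: 3, tags: [omega-6]}
    - {carbons: 20, double_bonds: 4, tags: [omega-6]}
    - {carbons: 20, double_bonds: 4, tags: [omega-3]}
    - {carbons: 20, double_bonds: 5, tags: [omega-3]}
    - {carbons: 22, double_bonds: 4, tags: [omega-6]}
    - {carbons: 22, double_bonds: 5, tags: [omega-6]}
    - {carbons: 22, double_bonds: 5, tags: [omega-3]}
    - {carbons: 22, double_bonds: 6, tags: [omega-3]}
    - {carbons: 24, double_bonds: 4, tags: [omega-6]}
    - {carbons: 24, double_bonds: 5, tags: [omega-6]}
    - {carbons: 24, double_bonds: 5, tags: [omega-3]}
    - {carbons: 24, double_bonds: 6, tags: [omega-3]}
  reactions:
    # de novo C2 elongations
    - {from: [2, 0],  to: [4, 0],  type: elongation}
    - {from: [4, 0],  to: [6, 0],  type: elongation}
    - {from: [6, 0],  to: [8, 0],  type: elongation}
    - {from: [8, 0],  to: [10, 0], type: elongation}
    - {from: [10, 0], to: [12, 0], type: elongation}
    - {from: [12, 0], to: [14, 0], type: elongation}
    - {from: [14, 0], to: [16, 0], type: elongation}
    - {from: [16, 0], to: [18, 0], type: elongation}
    - {from: [18, 0], to: [20, 0], type: elongation}
    - {from: [20, 0], to: [22, 0], type: elongation}
    - {from: [22, 0], to: [24, 0], type: elongation}
    - {from: [24, 0], to: [26, 0], type: elongation}
    # SCD desaturations and monounsaturated elongations
    - {from: [16, 0], to: [16, 1], type: desaturation}
    - {from: [18, 0], to: [18, 1], type: desaturation}
    - {from: [18, 1], to: [20, 1], type: elongation}
    - {from: [20, 1], to: [22, 1], type: elongation}
    - {from: [22, 1], to: [24, 1], type: elongation}
    # omega-6 pathway (from linoleic acid C18:2)
    - {from: [18, 2], to: [18, 3], type: desaturation}
    - {from: [18, 3], to: [20, 3], type: elongation}
    - {from: [20, 3], to: [20, 4], type: desaturation}
    - {from: [20, 4], to: [22, 4], type: elongation}
    - {from: [22, 4], to: [24, 4], type: elongation}
    - {from: [24, 4], to: [24, 5], type: desaturation}
    - {from: [24, 5], to: [22, 5], type: beta_oxidation}
    # omega-3 pathway (from alpha-linolenic acid C18:3)
    - {from: [18, 3], to: [18, 4], type: desaturation}
    - {from: [18, 4], to: [20, 4], type: elongation}
    - {from: [20, 4], to: [20, 5], type: desaturation}
    - {from: [20, 5], to: [22, 5], type: elongation}
    - {from: [22, 5], to: [24, 5], type: elongation}
    - {from: [24, 5], to: [24, 6], type: desaturation}
    - {from: [24, 6], to: [22, 6], type: beta_oxidation}

beta_oxidation:
  fatty_acids:
    - {carbons: 2,  double_bonds: 0, tags: [beta-oxidation]}
    - {carbons: 4,  double_bonds: 0, tags: [beta-oxidation]}
    - {carbons: 6,  double_bonds: 0, tags: [beta-oxidation]}
    - {carbons: 8,  double_bonds: 0, tags: [beta-oxidation]}
    - {carbons: 10, double_bonds: 0, tags: [beta-oxidation]}
    - {carbons: 12, double_bonds: 0, tags: [beta-oxidation]}
    - {carbons: 14, double_bonds: 0, tags: [beta-oxidation]}
    - {carbons: 16, double_bonds: 0, tags: [beta-oxidation]}
    - {carbons: 18, double_bonds: 0, tags: [beta-oxidation]}
    - {carbons: 10, double_bonds: 1, tags: [beta-oxidation]}
    - {carbons: 12, double_bonds: 1, tags: [beta-oxidation]}
    - {carbons: 14, double_bonds: 1, tags: [beta-oxidation]}
    - {carbons: 16, double_bonds: 1, tags: [beta-oxidation]}
    - {carbons: 18, double_bonds: 1, tags: [beta-oxidation]}
    - {carbons: 10, double_bonds: 2, tags: [beta-oxidation]}
    - {carbons: 12, double_bonds: 2, tags: [beta-oxidation]}
    - {carbons: 14, double_bonds: 2, tags: [beta-oxidation]}
    - {carbons: 16, double_bonds: 2, tags: [beta-oxidation]}
    - {carbons: 18, double_bonds: 2, tags: [beta-oxidation]}
  reactions:
    - {from: [18, 0], to: [16, 0], type: beta_oxidation}
    - {from: [16, 0], to: [14, 0], type: beta_oxidation}
    - {from: [14, 0], to: [12, 0], type: beta_oxidation}
    - {from: [12, 0], to: [10, 0], type: beta_oxidation}
    - {from: [10, 0], to: [8, 0],  type: beta_oxidation}
    - {from: [8, 0],  to: [6, 0],  type: beta_oxidation}
    - {from: [6, 0],  to: [4, 0],  type: beta_oxidation}
    - {from: [4, 0],  to: [2, 0],  type: beta_oxidation}
    - {from: [18, 1], to: [16, 1], type: beta_oxidation}
    - {from: [16, 1], to: [14, 1], type: beta_oxidation}
    - {from: [14, 1], to: [12, 1], type: beta_oxidation}
    - {from: [12, 1], to: [10, 1], type: beta_oxidation}
    - {from: [18, 2], to: [16, 2], type: beta_oxidation}
    - {from: [16, 2], to: [14, 2], type: beta_oxidation}
    - {from: [14, 2], to: [12, 2], type: beta_oxidation}
    - {from: [12, 2], to: [10, 2], type: beta_oxidation}
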