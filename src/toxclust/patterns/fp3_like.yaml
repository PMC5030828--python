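# Compact functional-group SMARTS list (fp3-like tier: broad, generic groups).
# Hand-written named patterns; not a bit-for-bit copy of any toolkit asset.
name: fp3
features:
  - {key: alcohol, smarts: "[CX4][OX2H]", description: aliphatic hydroxyl}
  - {key: phenol, smarts: "c[OX2H]", description: aromatic hydroxyl}
  - {key: ether, smarts: "[OD2]([#6])[#6]", description: ether oxygen between two carbons}
  - {key: aryl_ether, smarts: "c[OD2][#6]", description: aryl ether}
  - {key: aldehyde, smarts: "[CX3H1](=O)[#6]", description: aldehyde}
  - {key: ketone, smarts: "[#6][CX3](=O)[#6]", description: ketone}
  - {key: carboxylic_acid, smarts: "[CX3](=O)[OX2H1]", description: carboxylic acid}
  - {key: carboxylate, smarts: "[CX3](=O)[O-]", description: carboxylate anion}
  - {key: ester, smarts: "[CX3](=O)[OX2][#6]", description: carboxylic ester}
  - {key: lactone, smarts: "[C;R](=O)[O;R]", description: cyclic ester}
  - {key: anhydride, smarts: "[CX3](=O)[OX2][CX3](=O)", description: acid anhydride}
  - {key: acyl_halide, smarts: "[CX3](=O)[F,Cl,Br,I]", description: acyl halide}
  - {key: amide, smarts: "[NX3][CX3](=O)", description: carboxamide}
  - {key: urea, smarts: "[NX3][CX3](=O)[NX3]", description: urea}
  - {key: thiourea, smarts: "[NX3][CX3](=S)[NX3]", description: thiourea}
  - {key: carbamate, smarts: "[NX3][CX3](=O)[OX2]", description: carbamate}
  - {key: guanidine, smarts: "[NX3][CX3](=[NX2])[NX3]", description: guanidine}
  - {key: amidine, smarts: "[NX3][CX3]=[NX2]", description: amidine}
  - {key: primary_amine, smarts: "[NX3;H2][#6]", description: primary amine}
  - {key: secondary_amine, smarts: "[NX3;H1]([#6])[#6]", description: secondary amine}
  - {key: tertiary_amine, smarts: "[NX3]([#6])([#6])[#6]", description: tertiary amine}
  - {key: aromatic_amine, smarts: "c[NX3]", description: amine on aromatic ring}
  - {key: quaternary_n, smarts: "[NX4+]", description: quaternary nitrogen cation}
  - {key: nitro, smarts: "[$([NX3](=O)=O),$([NX3+](=O)[O-])]", description: nitro group}
  - {key: nitroso, smarts: "[NX2]=[OX1]", description: nitroso}
  - {key: nitrile, smarts: "[NX1]#[CX2]", description: nitrile}
  - {key: azo, smarts: "[#6][NX2]=[NX2][#6]", description: azo}
  - {key: hydrazine, smarts: "[NX3][NX3]", description: hydrazine}
  - {key: hydroxylamine, smarts: "[NX3][OX2H]", description: hydroxylamine}
  - {key: oxime, smarts: "[CX3]=[NX2][OX2H]", description: oxime}
  - {key: imine, smarts: "[CX3]=[NX2]", description: imine}
  - {key: isocyanate, smarts: "[NX2]=[CX2]=[OX1]", description: isocyanate}
  - {key: isothiocyanate, smarts: "[NX2]=[CX2]=[SX1]", description: isothiocyanate}
  - {key: thiol, smarts: "[SX2H]", description: thiol}
  - {key: thioether, smarts: "[SX2]([#6])[#6]", description: thioether}
  - {key: sulfoxide, smarts: "[SX3](=O)", description: sulfoxide}
  - {key: sulfone, smarts: "[SX4](=O)(=O)", description: sulfone}
  - {key: sulfonic_acid, smarts: "[SX4](=O)(=O)[OX2H]", description: sulfonic acid}
  - {key: sulfonamide, smarts: "[SX4](=O)(=O)[NX3]", description: sulfonamide}
  - {key: phosphorus_oxo, smarts: "[PX4](=O)", description: P(V) oxo group}
  - {key: fluoro, smarts: "[F]", description: fluorine}
  - {key: chloro, smarts: "[Cl]", description: chlorine}
  - {key: bromo, smarts: "[Br]", description: bromine}
  - {key: iodo, smarts: "[I]", description: iodine}
  - {key: aryl_halide, smarts: "c[F,Cl,Br,I]", description: halogen on aromatic ring}
  - {key: benzene_ring, smarts: "c1ccccc1", description: benzene ring}
  - {key: aromatic_n, smarts: "n", description: aromatic nitrogen}
  - {key: aromatic_o, smarts: "o", description: aromatic oxygen}
  - {key: aromatic_s, smarts: "s", description: aromatic sulfur}
  - {key: alkene, smarts: "[CX3]=[CX3]", description: C=C double bond}
  - {key: alkyne, smarts: "[CX2]#[CX2]", description: C#C triple bond}
  - {key: epoxide, smarts: "C1OC1", description: epoxide ring}
  - {key: peroxide, smarts: "[OX2][OX2]", description: peroxide}
  - {key: primary_alcohol, smarts: "[CH2][OX2H]", description: primary alcohol}
  - {key: anion, smarts: "[-]", description: any anionic atom}
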