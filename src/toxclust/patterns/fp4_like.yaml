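# Named structural-alert SMARTS list (fp4-like tier: more specific motifs,
# ring/topology descriptors, and the group names used in cluster reporting).
# Hand-written named patterns; not a bit-for-bit copy of any toolkit asset.
name: fp4
features:
  - {key: nitro_onoc, smarts: "[#8]~[#7](~[#8])~[#6]", description: "nitro-group motif O-N(O)-C, element-generic so charged and hypervalent forms both match"}
  - {key: nitro_aromatic, smarts: "[$([NX3](=O)=O),$([NX3+](=O)[O-])]c", description: nitro on aromatic carbon}
  - {key: nitro_aliphatic, smarts: "[$([NX3](=O)=O),$([NX3+](=O)[O-])][CX4]", description: nitro on sp3 carbon}
  - {key: nitroaniline, smarts: "[NX3;H2,H1]c1ccc(cc1)[$([NX3](=O)=O),$([NX3+](=O)[O-])]", description: para-nitroaniline motif}
  - {key: nitrophenol, smarts: "[OX2H]c1ccc(cc1)[$([NX3](=O)=O),$([NX3+](=O)[O-])]", description: para-nitrophenol motif}
  - {key: carboxylic_acid_derivative, smarts: "[CX3](=[OX1])[#7,#8,F,Cl,Br,I]", description: acid derivative C(=O)-X}
  - {key: amine, smarts: "[NX3;!$(NC=O);!$(N=O);!$(N[O-])]", description: amine nitrogen (not amide/nitro)}
  - {key: ketone, smarts: "[#6][CX3](=O)[#6]", description: ketone}
  - {key: vinylogous_ester, smarts: "[CX3](=[OX1])[CX3]=[CX3][OX2]", description: vinylogous ester}
  - {key: heterocyclic, smarts: "[!#6;R]", description: heteroatom in a ring}
  - {key: aromatic, smarts: a, description: any aromatic atom}
  - {key: heteroaromatic, smarts: "[a;!c]", description: aromatic heteroatom}
  - {key: annelated_rings, smarts: "[R2]", description: atom shared by two rings (fused system)}
  - {key: conjugated_double_bond, smarts: "[CX3]=[CX3][CX3]=[CX3]", description: conjugated diene}
  - {key: alcohol, smarts: "[OX2H][CX4]", description: aliphatic alcohol}
  - {key: glycol, smarts: "[OX2H][CX4][CX4][OX2H]", description: 1,2-diol}
  - {key: glycol_ether, smarts: "[OX2H][CX4][CX4][OD2][#6]", description: glycol monoether motif}
  - {key: dialkyl_ether, smarts: "[CX4][OD2][CX4]", description: dialkyl ether}
  - {key: polyether, smarts: "[#6][OD2][#6][#6][OD2][#6]", description: repeated ether linkage}
  - {key: hbd, smarts: "[#7!H0,#8!H0]", description: hydrogen-bond donor (N-H or O-H)}
  - {key: hba, smarts: "[#7X3,#8X2;!$([OX2H0]=*)]", description: hydrogen-bond acceptor}
  - {key: c_o_single_bond, smarts: C-O, description: carbon-oxygen single bond}
  - {key: ring5, smarts: "*1****1", description: any five-membered ring}
  - {key: ring6, smarts: "*1*****1", description: any six-membered ring}
  - {key: methyl_on_aromatic, smarts: "[CH3]c", description: methyl on aromatic ring}
  - {key: toluene_motif, smarts: "[CH3]c1ccccc1", description: methylbenzene}
  - {key: cresol_motif, smarts: "[CH3]c1ccccc1O", description: methylphenol motif}
  - {key: aniline, smarts: "[NX3;H2]c1ccccc1", description: aniline}
  - {key: benzylic_ch, smarts: "[CX4H2]c", description: benzylic methylene}
  - {key: halogenated_aromatic, smarts: "c[F,Cl,Br,I]", description: halogen on aromatic ring}
  - {key: dichloro_aromatic, smarts: "Clc1ccccc1Cl", description: ortho-dichlorobenzene motif}
  - {key: trihalomethyl, smarts: "[CX4]([F,Cl,Br,I])([F,Cl,Br,I])[F,Cl,Br,I]", description: trihalomethyl group}
  - {key: imidazole, smarts: "c1cnc[nH]1", description: imidazole ring}
  - {key: n_alkyl_imidazole, smarts: "c1cncn1[#6]", description: N-substituted imidazole}
  - {key: triazole, smarts: "c1ncn[nH]1", description: 1,2,4-triazole ring}
  - {key: pyridine, smarts: "c1ccncc1", description: pyridine ring}
  - {key: pyrimidine, smarts: "c1cncnc1", description: pyrimidine ring}
  - {key: furan, smarts: "c1ccoc1", description: furan ring}
  - {key: thiophene, smarts: "c1ccsc1", description: thiophene ring}
  - {key: pyrrole, smarts: "c1cc[nH]c1", description: pyrrole ring}
  - {key: mercaptoimidazole, smarts: "Sc1ncc[nH]1", description: 2-mercaptoimidazole motif}
  - {key: phenolate, smarts: "c[O-]", description: phenolate}
  - {key: quinone, smarts: "O=C1C=CC(=O)C=C1", description: para-quinone}
  - {key: azide, smarts: "[NX2]=[NX2+]=[NX1-]", description: azide}
  - {key: nitrate_ester, smarts: "[#6]O[NX3](=O)=O", description: nitrate ester}
  - {key: n_nitroso, smarts: "[NX3][NX2]=[OX1]", description: N-nitroso}
  - {key: aryl_azo, smarts: "c[NX2]=[NX2]c", description: aromatic azo}
  - {key: benzidine_like, smarts: "c1ccc(cc1)-c1ccccc1", description: biphenyl linkage}
  - {key: michael_acceptor, smarts: "[CX3]=[CX3][CX3]=[OX1]", description: alpha,beta-unsaturated carbonyl}
  - {key: allyl_alcohol_motif, smarts: "[CX3]=[CX3][CX4][OX2H]", description: allylic alcohol}
  - {key: propargylic_alcohol, smarts: "[CX2]#[CX2][CX4][OX2H]", description: propargylic alcohol}
  - {key: tert_alcohol, smarts: "[CX4]([#6])([#6])([#6])[OX2H]", description: tertiary alcohol}
  - {key: sec_alcohol, smarts: "[CX4H1]([#6])([#6])[OX2H]", description: secondary alcohol}
  - {key: thioglycol, smarts: "[OX2H][CX4][CX4][SX2]", description: thiodiglycol motif}
  - {key: long_chain, smarts: "[CX4][CX4][CX4][CX4][CX4][CX4]", description: six consecutive sp3 carbons}
  - {key: branched_carbon, smarts: "[CX4]([#6])([#6])([#6])[#6]", description: quaternary-substituted sp3 carbon}
  - {key: alpha_halo_carbonyl, smarts: "[F,Cl,Br,I][CX4][CX3]=[OX1]", description: alpha-halo carbonyl alert}
  - {key: epoxide_alert, smarts: "C1OC1", description: epoxide alert}
  - {key: aldehyde_alert, smarts: "[CX3H1]=[OX1]", description: aldehyde alert}
  - {key: isocyanate_alert, smarts: "[NX2]=[CX2]=[OX1]", description: isocyanate alert}
  - {key: sulfonate_ester, smarts: "[SX4](=O)(=O)[OX2][#6]", description: sulfonate ester alert}
  - {key: phosphate_ester, smarts: "[PX4](=O)([OX2][#6])", description: phosphate ester}
  - {key: perhalo_alkyl, smarts: "[CX4]([F,Cl])([F,Cl])[CX4]([F,Cl])[F,Cl]", description: perhaloalkyl chain}
  - {key: thiocarbonyl, smarts: "[CX3]=[SX1]", description: thiocarbonyl}
  - {key: carbonate, smarts: "[OX2][CX3](=[OX1])[OX2]", description: carbonate}
  - {key: acetal, smarts: "[CX4]([OD2][#6])[OD2][#6]", description: acetal}
  - {key: enol_ether, smarts: "[CX3]=[CX3][OD2][#6]", description: enol ether}
  - {key: aminophenol, smarts: "[NX3;H2,H1]c1ccccc1[OX2H]", description: ortho-aminophenol motif}
  - {key: catechol, smarts: "[OX2H]c1ccccc1[OX2H]", description: catechol}
  - {key: methylenedioxy, smarts: "C1Oc2ccccc2O1", description: methylenedioxyphenyl}
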