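# Xenon contact-site clusters: for each named site, the three residues
# most often contacted (receptor numbering; NPY_* sites refer to the
# ligand peptide).  Two systems: the conjugate alone (apo) and the
# conjugate in complex with neuropeptide Y (npy).
apo:
  NTER: [L40, I41, K45]
  ECL1: [L112, M113, G114]
  ECL2_1: [I195, P196, F198]
  ECL2_2: [W207, P208, G209]
  ECL3: [Q296, D299, L300]
npy:
  NTER: [L40, I41, S43]
  ECL2_1: [I195, P196, F198]
  ECL3: [L300, K301, E302]
  NPY_NTER: [G9, E10, A12]
  NPY_helix: [A14, M17, Y21]
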