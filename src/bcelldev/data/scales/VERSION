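bcelldev-scales 1.0
kyte_doolittle: Kyte & Doolittle hydropathy (1982)
boman: Boman protein-binding potential scale (2003), side-chain water/cyclohexane transfer free energies
kidera: Kidera orthogonal factors KF1-KF10 (1985), normalized over the 20 residues
residue_masses: average residue masses (Da); peptide mass adds one water (18.01524 Da)
pka_emboss: EMBOSS iep pKa set
classes: nine-class amino-acid composition convention
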