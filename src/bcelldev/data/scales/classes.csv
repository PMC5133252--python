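class,residues
tiny,ACGST
small,ACDGNPSTV
aliphatic,AILV
aromatic,FHWY
nonpolar,ACFGILMPVWY
polar,DEHKNQRST
charged,DEHKR
basic,HKR
acidic,DE
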