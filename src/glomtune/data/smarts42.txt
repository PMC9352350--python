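# SMARTS42 substructure keyset: one SMARTS pattern per line, fixed order.
# Bit k of a fingerprint is 1 iff the molecule contains >=1 match of pattern k.
# Lines starting with '#' and blank lines are ignored; an inline '\t' separates
# the pattern from its human-readable label.
*-C(=O)-[OH1]	carboxylic acid
[CH1]=O	aldehyde
C-C(=O)-[O]-C	ester
C-C(=O)-[S]-C	thioester
[!O&!S]-C(=O)-[!O&!S]	ketone
[OX2H][CX4&!$(C([OX2H])[O,S,#7,#15]),c]	alcohol
c1ccccc1	benzyl
C~C(~C)~C-C~C-C(~C)~C	monoterpene
[#8]1~[#6]~[#6]~[#6]~[#6]1	furanoid
o1cccc1	furan
[NH2][C]	primary amine
[NH](C)C	secondary amine
[NH0](C)(C)C	tertiary amine
[N,n]1~[C,c]~[C,c]~[C,c]~[C,c]~[C,c]1	pyridine
[n,N]1~[C,c]~[C,c]~[C,c]~[C,c]1	pyrrole
[N,n]1~[C,c]~[C,c]~[N,n]~[C,c]~[C,c]1	pyrazine
[#16]1~[#6]~[#7]~[#6]~[#6]1	thiazoline
[!#8]~C-S-C~[!#8]	thioether
[$(C-S-S-C),$(C-S-S-S-C)]	sulfide
[#6]-[SH]	thiol
[#6]=[#6]	alkene
[#16]	sulfur
[#7]	nitrogen
[#8]	oxygen
[R]	ring
[CH3]-*-[CH2]-*	4-bond chain with C at 1 and 3
*!@*@*!@*	ortho-substituted rings
*!@*@*@*!@*	meta-substituted rings
*1(!@*)@*@*@*(!@*)@*@*@1	para substituted 6-ring but not fused ring
C~C(~C)~[R1]1~[R1]~[R1]~[R1](~C)~[R1]~[R1]~1	menthane scaffold
C~C(~C)~2-[R2]1~[R2]~2-[R1]~[R1](~C)~[R1]~[R1]~1	carene scaffold
C~C(~C)~[R2]12~[R1]~[R2]~2-[R1](~C)~[R1]~[R1]~1	thujane scaffold
C~C2(~C)~[R]1~[R]~[R]~2-[R](~C)~[R]~[R]~1	pinane scaffold
[!H]~[!H]2(~[!H])~[R]1~[R]~[R]~[R](~[!H])~2-[R]~[R]~1	camphane scaffold
[!H]~[!H]2(~[!H])~[R]~[R](~[!H])1~[R]~[R]~2-[R]~[R]~1	fenchane scaffold
C(-C)(-C)(-C)-C	quaternary carbon
C-C-C-C-C-C	six carbon single bond chain
C-C-C-C-C-C-C	seven carbon single bond chain
C-C-C-C-C-C-C-C	eight carbon single bond chain
C-C-C-C-C-C-C-C-C	nine carbon single bond chain
C-C-C-C-C-C-C-C-C-C	ten carbon single bond chain
C-C-C-C-C-C-C-C-C-C-C	eleven carbon single bond chain
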