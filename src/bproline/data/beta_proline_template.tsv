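# beta-proline residue template, version 1.0
# 5-phenylpyrrolidine-2-carboxylate unit of an alternating beta-proline
# oligopeptide. Backbone runs N-CA-CB with the amide carbonyl C/O carried by
# CB; the phenyl substituent sits on CA and the methoxycarbonyl ester on CD,
# following the Greek-letter atom notation (phenyl at the alpha position,
# ester at the delta position). Note: the systematic monomer name
# "5-phenylpyrrolidine-2-carboxylate" admits the alternative reading with the
# positions swapped (phenyl at ring position 5, carboxylate at position 2);
# this template fixes the Greek-letter convention.
#
# kind=ring   : five-membered ring atom; "length" is the bond to the previous
#               ring atom in the cycle N-CA-CB-CG-CD(-N).
# kind=sub    : exocyclic substituent placed on a ring carbon symmetrically
#               about the local ring tangent; "side" is the chirality sign of
#               the canonical (unmirrored) residue; "torsion" (optional) is a
#               rocking rotation of the substituent pair about the exocyclic
#               bisector, used for the Cgamma methylene.
# kind=zmat   : atom placed from internal coordinates (parent, ref1, ref2,
#               length, angle, torsion).
# kind=ncap   : N-terminal acyl cap, first atom placed in the amide plane of
#               the ring nitrogen; remainder zmat. Present on residue 1 only.
# kind=cterm  : C-terminal tert-butyl ester on the last residue's carbonyl.
#               The ester oxygen OT replaces the amide nitrogen of the next
#               residue; its torsion about CB-C is set at assembly time.
# Angstrom / degree units throughout.
kind	atom	element	parent	ref1	ref2	side	length	angle	torsion
ring	N	N	.	.	.	.	1.45	.	.
ring	CA	C	N	.	.	.	1.45	.	.
ring	CB	C	CA	.	.	.	1.53	.	.
ring	CG	C	CB	.	.	.	1.53	.	.
ring	CD	C	CG	.	.	.	1.53	.	.
sub	CP1	C	CA	.	.	1	1.51	.	.
sub	HA	H	CA	.	.	-1	1.09	.	.
sub	C	C	CB	.	.	1	1.52	.	.
sub	HB	H	CB	.	.	-1	1.09	.	.
sub	HG2	H	CG	.	.	1	1.09	.	8.0
sub	HG3	H	CG	.	.	-1	1.09	.	8.0
sub	CE	C	CD	.	.	1	1.52	.	.
sub	HD	H	CD	.	.	-1	1.09	.	.
zmat	CP2	C	CP1	CA	N	.	1.39	120.0	45.0
zmat	CP3	C	CP2	CP1	CA	.	1.39	120.0	180.0
zmat	CP4	C	CP3	CP2	CP1	.	1.39	120.0	0.0
zmat	CP5	C	CP4	CP3	CP2	.	1.39	120.0	0.0
zmat	CP6	C	CP5	CP4	CP3	.	1.39	120.0	0.0
zmat	HP2	H	CP2	CP1	CA	.	1.08	120.0	-135.0
zmat	HP3	H	CP3	CP2	CP1	.	1.08	120.0	180.0
zmat	HP4	H	CP4	CP3	CP2	.	1.08	120.0	180.0
zmat	HP5	H	CP5	CP4	CP3	.	1.08	120.0	180.0
zmat	HP6	H	CP6	CP5	CP4	.	1.08	120.0	180.0
zmat	OE1	O	CE	CD	N	.	1.21	125.0	-45.0
zmat	OE2	O	CE	CD	N	.	1.34	111.0	135.0
zmat	CM	C	OE2	CE	CD	.	1.43	116.0	180.0
zmat	HM1	H	CM	OE2	CE	.	1.09	109.5	60.0
zmat	HM2	H	CM	OE2	CE	.	1.09	109.5	180.0
zmat	HM3	H	CM	OE2	CE	.	1.09	109.5	-60.0
ncap	CCAP	C	N	CA	CD	.	1.36	.	.
ncap	OCAP	O	CCAP	N	CA	.	1.23	123.0	0.0
ncap	CMC	C	CCAP	N	CA	.	1.50	115.0	180.0
ncap	HC1	H	CMC	CCAP	N	.	1.09	109.5	60.0
ncap	HC2	H	CMC	CCAP	N	.	1.09	109.5	180.0
ncap	HC3	H	CMC	CCAP	N	.	1.09	109.5	-60.0
cterm	OT	O	C	CB	CA	.	1.34	114.0	.
cterm	CT	C	OT	C	CB	.	1.47	120.0	180.0
cterm	CT1	C	CT	OT	C	.	1.53	109.5	60.0
cterm	CT2	C	CT	OT	C	.	1.53	109.5	180.0
cterm	CT3	C	CT	OT	C	.	1.53	109.5	-60.0
cterm	HT11	H	CT1	CT	OT	.	1.09	109.5	60.0
cterm	HT12	H	CT1	CT	OT	.	1.09	109.5	180.0
cterm	HT13	H	CT1	CT	OT	.	1.09	109.5	-60.0
cterm	HT21	H	CT2	CT	OT	.	1.09	109.5	60.0
cterm	HT22	H	CT2	CT	OT	.	1.09	109.5	180.0
cterm	HT23	H	CT2	CT	OT	.	1.09	109.5	-60.0
cterm	HT31	H	CT3	CT	OT	.	1.09	109.5	60.0
cterm	HT32	H	CT3	CT	OT	.	1.09	109.5	-60.0
cterm	HT33	H	CT3	CT	OT	.	1.09	109.5	180.0
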