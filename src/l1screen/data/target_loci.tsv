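# Target site loci for the multiplex insertion screen.
# amplicon_length_bp is the full target amplicon length (bp); x_linked loci are
# present in only half of sperm.
name	chromosome	amplicon_length_bp	x_linked
DMD	X	4909	1
F9	X	5552	1
CHM	X	5678	1
CYBB	X	5160	1
RP2	X	4774	1
HBB	11	5006	0
FKTN	9	5019	0
APC	5	5417	0
HOXD	2	4286	0
MHC2	6	5018	0
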