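gene	kind	expected_introns	trans_spliced
trnA-UGC	tRNA	1	0
trnI-GAU	tRNA	1	0
trnK-UUU	tRNA	1	0
trnL-UAA	tRNA	1	0
trnV-UAC	tRNA	1	0
atpF	PCG	1	0
clpP	PCG	2	0
ndhA	PCG	1	0
ndhB	PCG	1	0
petB	PCG	1	0
petD	PCG	1	0
rpl16	PCG	1	0
rpl2	PCG	1	0
rpoC1	PCG	1	0
rps12	PCG	1	1
rps16	PCG	1	0
ycf3	PCG	2	0
infA	PCG	0	0
rpl32	PCG	0	0
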