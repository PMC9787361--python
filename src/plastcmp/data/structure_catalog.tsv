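code	isotype	feature	value
A1	tRNA-Ser-UGA	v_loop	GAACAA
A2	tRNA-Ser-UGA	v_loop	UUUGUUCA
A3	tRNA-Ser-UGA	v_loop	CUUGUUCA
A4	tRNA-Ser-UGA	v_loop	GAAACAAA
A5	tRNA-Ser-UGA	v_loop	UAAACAAA
A6	tRNA-Ser-UGA	v_loop	GAAUAA
B1	tRNA-Ser-GCU	v_loop	GUUAU
B2	tRNA-Ser-GCU	v_loop	GCGAU
B3	tRNA-Ser-GCU	v_loop	UCGAU
B4	tRNA-Ser-GCU	v_loop	GCUAU
B5	tRNA-Ser-GCU	v_loop	GUGAU
B6	tRNA-Ser-GCU	v_loop	GUUUU
B7	tRNA-Ser-GCU	v_loop	UUA
C1	tRNA-Tyr-GUA	v_loop	AUA
C2	tRNA-Tyr-GUA	v_loop	AAAAU
D1	tRNA-Thr-UGU	ac_extra	CU
D2	tRNA-Thr-UGU	ac_extra	CC
D3	tRNA-Thr-UGU	ac_extra	none
D4	tRNA-Thr-UGU	t_extra	GG
D5	tRNA-Thr-UGU	ac_extra	UU
E1	tRNA-Val-UAC	anc_loop	9
E2	tRNA-Val-UAC	anc_loop	7
F1	tRNA-Leu-UAA	anc_loop	9
F2	tRNA-Leu-UAA	anc_loop	7
G1	tRNA-Leu-CAA	v_loop	AAAG
G2	tRNA-Leu-CAA	v_loop	CAAG
G3	tRNA-Leu-CAA	v_loop	AAAC
G4	tRNA-Leu-CAA	v_loop	AAAU
H1	tRNA-Ser-GGA	v_loop	UUUU
H2	tRNA-Ser-GGA	v_loop	GUUU
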