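gene	protein_name	start	end	domain_id	domain_name
CREB	cAMP response element-binding protein	87	146	IPR003102	Coactivator CBP, pKID
CREB	cAMP response element-binding protein	284	342	IPR004827	Basic-leucine zipper domain
FOXD3	Forkhead box D3	71	173	IPR011991	Winged helix-turn-helix DNA binding domain
LEF1	Lymphoid enhancer-binding factor 1	1	65	IPR027397	Catenin binding domain
LEF1	Lymphoid enhancer-binding factor 1	1	209	IPR013558	CTNNB1 binding, N-terminal
LEF1	Lymphoid enhancer-binding factor 1	293	375	IPR009071	High mobility group box domain
MITF	Microphthalmia-associated transcription factor	303	370	IPR011598	Myc-type, basic helix-loop-helix (bHLH) domain
MITF	Microphthalmia-associated transcription factor	393	519	IPR021802	MiT/TFE transcription factors, C-terminal
MITF	Microphthalmia-associated transcription factor	4	142	IPR031867	MiT/TFE transcription factors, N-terminal
POU3F2	POU Class 3 Homeobox 2	51	125	IPR000327	POU-specific domain
POU3F2	POU Class 3 Homeobox 2	125	205	IPR009057	Homeodomain-like
USF1	Upstream transcription factor 1	193	286	IPR011598	Myc-type, basic helix-loop-helix (bHLH) domain
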