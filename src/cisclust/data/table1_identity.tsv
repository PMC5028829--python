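gene	pyth2hum	pyth2mouse	pyth2dog	pyth2horse	pyth2cow	pyth2chick	pyth2anole	pyth2Tham_sirt
ASIP	46	39	45	39	48	52	79	86
KIT	64	64	64	64	65	71	83	89
MGRN1	74	73	77	73	74	78	80	92
PMEL	40	48	39	41	39	50	66	77
OCA2	86	83	86	86	73	89	93	82
MYO5A	89	88	88	86	89	89	92	82
TRPM1	76	74	76	76	76	84	86	91
RAB27A	90	92	90	92	91	93	94	95
SLC24A5	76	71	75	76	75	77	85	0
EDN3	42	41	43	48	42	64	60	78
MITF	80	77	80	79	72	88	94	94
SLC2A9	68	67	68	71	68	73	83	88
RAB38	74	76	76	78	78	82	83	0
PAX3	98	96	97	97	99	97	99	99
ATRN	79	80	80	95	77	83	87	91
OSTM1	62	57	59	62	57	60	66	86
MCOLN3	82	80	82	78	81	85	90	95
KITLG	40	49	46	46	46	62	73	85
TYR	71	72	73	73	74	76	81	87
LYST	64	62	63	63	63	67	79	92
SOX10	82	83	83	79	82	95	97	99
STX17	74	71	74	74	74	76	81	87
EDNRB	64	61	62	61	60	80	79	64
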