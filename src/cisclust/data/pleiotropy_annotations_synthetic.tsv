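# Synthetic annotation fixture: short pleiotropy tags per coat-color gene,
# paraphrased from the mammalian coat-color literature, used only to
# exercise heat-map row-label formatting ("GENE (annotation)").
gene	annotation
ASIP	obesity
KIT	sterility, white spotting
MGRN1
PMEL	silver hair
OCA2	albinism
MYO5A	lethality
TRPM1	leopard complex spotting
RAB27A	immune dysfunction
SLC24A5
EDN3	deafness
MITF	deafness, white coat
SLC2A9	metabolic
RAB38
PAX3	deafness, white coat
ATRN
OSTM1
MCOLN3
KITLG	sterility
TYR	oculocutaneous albinism
LYST	Chediak-Higashi syndrome
SOX10	deafness
STX17
EDNRB	deafness, megacolon
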