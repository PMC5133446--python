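# Dual-reporter readthrough measurements used to fit the packaged default
# RTP model.  The wild-type row and the stop/+4/+5/+6 mutant series follow
# the published MDH1 SCC reporter series (WT 4.34%; stop and +4 mutants at
# the <0.1% background; +5/+6 mutants between 0.4 and 0.8%).  The +7 rows
# are a synthetic calibration series (no +7 mutants were assayed) encoding
# the weaker, parenthesised G preference at +7 of the published consensus.
# upstream flank is the MDH1-like constant AACGGCAUCG for all rows.
label	stop	downstream	readthrough_percent
WT	UGA	CUAGAAGCAG	4.34
stop_UAA	UAA	CUAGAAGCAG	0.07
stop_UAG	UAG	CUAGAAGCAG	0.07
p4_C_to_A	UGA	AUAGAAGCAG	0.07
p4_C_to_G	UGA	GUAGAAGCAG	0.07
p4_C_to_U	UGA	UUAGAAGCAG	0.07
p5_U_to_A	UGA	CAAGAAGCAG	0.45
p5_U_to_C	UGA	CCAGAAGCAG	0.62
p5_U_to_G	UGA	CGAGAAGCAG	0.78
p6_A_to_C	UGA	CUCGAAGCAG	0.48
p6_A_to_G	UGA	CUGGAAGCAG	0.66
p6_A_to_U	UGA	CUUGAAGCAG	0.74
p7_G_to_A	UGA	CUAAAAGCAG	1.90
p7_G_to_C	UGA	CUACAAGCAG	2.10
p7_G_to_U	UGA	CUAUAAGCAG	2.00
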