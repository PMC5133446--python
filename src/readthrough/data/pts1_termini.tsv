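# Curated-style training fixture for the PTS1 scoring model: C-terminal
# 12-mers labelled 1 (peroxisomal PTS1-class terminus) or 0 (non-PTS1).
# Sequences are synthetic composites built around the canonical terminal
# tripeptide classes ([SAC][KRH][LM] positives; ER-retention and acidic
# cytosolic termini, and delta-L truncations, as negatives); they are not
# database accessions.
id	terminus	label
pos_skl_01	AKGLRSQIHSKL	1
pos_skl_02	MSENLKRSHSKL	1
pos_skl_03	GQRSTKLNQSKL	1
pos_skl_04	LTKERSNAVSKL	1
pos_skl_05	QNSPKAGLHSKL	1
pos_skl_06	RLPGTQKSNSKL	1
pos_skl_07	VSGAKRLTQSKL	1
pos_akl_01	NTRQLSGKHAKL	1
pos_akl_02	SKGPLNRTQAKL	1
pos_akl_03	TQLNSKRGPAKL	1
pos_srl_01	GKSLNTQRHSRL	1
pos_srl_02	PLKGQSTNRSRL	1
pos_srl_03	NQGKRLSPTSRL	1
pos_srl_04	SRTQGKLNPSRL	1
pos_crl_01	KLSPGNTRQCRL	1
pos_crl_02	TNGKQLRSPCRL	1
pos_crl_03	QSPLGKNRTCRL	1
pos_pkl_01	RGTNSLQKPPKL	1
pos_pkl_02	LNQSGRKTPPKL	1
pos_shl_01	KPTGSLQNRSHL	1
pos_shl_02	GSQNKPLRTSHL	1
pos_arl_01	TKLQPNGSRARL	1
pos_arl_02	QGNRSPKLTARL	1
pos_skm_01	SPQTKNGLRSKM	1
pos_anl_01	NKGSQPTRLANL	1
pos_ckl_01	RQSPNGKTLCKL	1
pos_ckl_02	LGQKTNSPRCKL	1
pos_snl_01	KNTSQGPRLSNL	1
pos_acox3_like	SQRLPKTNGSKL	1
pos_mdh1x_like	GVSNPQKTRCRL	1
neg_cyt_01	TLDGESNQPVDG	0
neg_cyt_02	SGEDLNTQPAGE	0
neg_cyt_03	QNDPESGTLVSD	0
neg_cyt_04	GELSDNQTPEEV	0
neg_cyt_05	NSGQDELTPIDE	0
neg_cyt_06	LDPQSGENTKDE	0
neg_kdel_er	AQSGTNLPKDEL	0
neg_hdel_er	GTNSQLPAHDEL	0
neg_ggl_01	SQGNTLDPEGGL	0
neg_eel_01	NTQSGPLDEEEL	0
neg_dL_skl	GQSTNRLPHASK	0
neg_dL_crl	KLSPGNTRQHCR	0
neg_dL_srl	GKSLNTQRHPSR	0
neg_cyt_07	QSGTNDLPEVTK	0
neg_cyt_08	GNSQLTDPEQRV	0
neg_cyt_09	TDEGSNQLPVVG	0
neg_cyt_10	SNQGDTLEPAAD	0
neg_cyt_11	LQGSNTDEPGFE	0
neg_cyt_12	NDSGQLTPEMVD	0
neg_cyt_13	GSTNQDLPEKAG	0
neg_cyt_14	QLGNSDTPEVSE	0
neg_cyt_15	TSNGQLDEPRGD	0
neg_cyt_16	DGQSNTLPEFAV	0
neg_cyt_17	SGNQTDLPEGMS	0
neg_cyt_18	NQSGLTDPEDTV	0
neg_cyt_19	GTQSNDLEPVLP	0
neg_cyt_20	QDNSGTLPEASG	0
neg_cyt_21	TGNQSDLPEWNE	0
neg_cyt_22	SDQGNTLEPHGT	0
neg_cyt_23	NGSQTDLPEYQD	0
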