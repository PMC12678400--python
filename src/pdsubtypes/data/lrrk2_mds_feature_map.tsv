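source	target	kind	derivation
NP1COG	mdsupdrs1_1	exact
NP1HALL	mdsupdrs1_2	exact
NP1DPRS	mdsupdrs1_3	exact
NP1ANXS	mdsupdrs1_4	exact
NP1APAT	mdsupdrs1_5	exact
NP1DDS	mdsupdrs1_6	exact
NP1SLPN	mdsupdrs1_7	exact
NP1SLPD	mdsupdrs1_8	exact
NP1PAIN	mdsupdrs1_9	exact
NP1URN	mdsupdrs1_10	exact
NP1CNST	mdsupdrs1_11	exact
NP1LTHD	mdsupdrs1_12	exact
NP1FATG	mdsupdrs1_13	exact
NP2SPCH	mdsupdrs2_1	exact
NP2SALV	mdsupdrs2_2	exact
NP2SWAL	mdsupdrs2_3	exact
NP2EAT	mdsupdrs2_4	exact
NP2DRES	mdsupdrs2_5	exact
NP2HYGN	mdsupdrs2_6	exact
NP2HWRT	mdsupdrs2_7	exact
NP2HOBB	mdsupdrs2_8	exact
NP2TURN	mdsupdrs2_9	exact
NP2TRMR	mdsupdrs2_10	exact
NP2RISE	mdsupdrs2_11	exact
NP2WALK	mdsupdrs2_12	exact
NP2FREZ	mdsupdrs2_13	exact
PDMEDYN	mdsupdrs3a	exact
PDCLNSTA	mdsupdrs3b	exact
LDOPARX	mdsupdrs3c	exact
MINSNCLD	mdsupdrs3c1	exact
NP3SPCH	mdsupdrs3_1	exact
NP3FACXP	mdsupdrs3_2	exact
NP3RIGN	mdsupdrs3_3a	exact
NP3RIGRU	mdsupdrs3_3b	exact
NP3RIGLU	mdsupdrs3_3c	exact
NP3RIGRL	mdsupdrs3_3d	exact
NP3RIGLL	mdsupdrs3_3e	exact
NP3FTAPR	mdsupdrs3_4a	exact
NP3FTAPL	mdsupdrs3_4b	exact
NP3HMOVR	mdsupdrs3_5a	exact
NP3HMOVL	mdsupdrs3_5b	exact
NP3PRSPR	mdsupdrs3_6a	exact
NP3PRSPL	mdsupdrs3_6b	exact
NP3TTAPR	mdsupdrs3_7a	exact
NP3TTAPL	mdsupdrs3_7b	exact
NP3LGAGR	mdsupdrs3_8a	exact
NP3LGAGL	mdsupdrs3_8b	exact
NP3RISNG	mdsupdrs3_9	exact
NP3GAIT	mdsupdrs3_10	exact
NP3FRZGT	mdsupdrs3_11	exact
NP3PSTBL	mdsupdrs3_12	exact
NP3POSTR	mdsupdrs3_13	exact
NP3BRADY	mdsupdrs3_14	exact
NP3PTRMR	mdsupdrs3_15a	exact
NP3PTRML	mdsupdrs3_15b	exact
NP3KTRMR	mdsupdrs3_16a	exact
NP3KTRML	mdsupdrs3_16b	exact
NP3RTARU	mdsupdrs3_17a	exact
NP3RTALU	mdsupdrs3_17b	exact
NP3RTARL	mdsupdrs3_17c	exact
NP3RTALL	mdsupdrs3_17d	exact
NP3RTALJ	mdsupdrs3_17e	exact
NP3RTCON	mdsupdrs3_18	exact
DYSKPRES	mdsupdrs_dysk	exact
DYSKIRAT	mdsupdrs_int	exact
NHY	mdsupdrs_hy	exact
NP4WDYSK	mdsupdrs4_1	exact
NP4DYSKI	mdsupdrs4_2	exact
NP4OFF	mdsupdrs4_3	exact
NP4FLCTI	mdsupdrs4_4	exact
NP4FLCTX	mdsupdrs4_5	exact
NP4DYSTN	mdsupdrs4_6	exact
NHY	hy	exact
MCATOT	moca	exact
Gender	sex	exact
Ageonset	pdonset	exact
totled	ldopadose_LED	exact
demopd_ageassess	Age	exact
PD_duration	durat_pd	derived	demopd_ageassess minus Ageonset
epworth_sum	epworth_score	derived	Product of mdsnms_K3f and mdsnms_K3s
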