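module_name	node_number	name	abbreviation	final_assignment	clustering_assignment
SSM	1	Left Face	Face_L	1	1
SSM	2	Right Face	Face_R	1	1
SSM	3	Left Hand	Hand_L	1	1
SSM	4	Right Hand	Hand_R	1	1
SSM	5	Left Leg	Leg_L	1	1
SSM	6	Right Leg	Leg_R	1	1
SSM	7	Left Parietal Operculum	PrOp_L	1	1
SSM	8	Right Parietal Operculum	PrOp_R	1	1
SSM	9	Left Superior Parietal Lobule	SPL_L	1	1
SSM	10	Right Superior Parietal Lobule	SPL_R	1	1
SSM	11	Left Dorsal Visual Stream	DVS_L	1	1
SSM	12	Right Dorsal Visual Stream	DVS_R	1	1
TIL	13	Left Auditory	Aud_L	2	2
TIL	14	Right Auditory	Aud_R	2	2
TIL	15	Left Superior Temporal	ST_L	2	2
TIL	16	Right Superior Temporal	ST_R	2	2
TIL	17	Posterior Language	Lang_P	2	2
TIL	18	Left Temporal Default Mode Network	tDMN_L	2	2
TIL	19	Right Temporal Default Mode Network	tDMN_R	2	2
TIL	20	Left Anterior Limbic Network	ALN_L	2	2
TIL	21	Right Anterior Limbic Network	ALN_R	2	2
TIL	22	Left Posterior Limbic Network	PLN_L	2	2
TIL	23	Right Posterior Limbic Network	PLN_R	2	2
TIL	24	Left Deep Gray	DG_L	2	2
TIL	25	Right Deep Gray	DG_R	2	2
TIL	26	Left Insula	Ins_L	2	2
TIL	27	Right Insula	Ins_R	2	2
TPN	28	Left Inferior Temporal	IT_L	3	3
TPN	29	Anterior Language	Lang_A	3	3
TPN	30	Anterior Right Working Memory	rWM_A	3	3
TPN	31	Posterior Right Working Memory	rWM_P	3	3
TPN	32	Posterior Left Working Memory	lWM_P	3	4
TPN	33	Left Attention	Att_L	3	3
TPN	34	Right Attention	Att_R	3	3
TPN	35	Anterior Cingulate Region of Salience Network	SN_ACC	3	3
TPN	36	Left Lateral Region of Salience Network	SN_L_Lat	3	3
TPN	37	Right Lateral Region of Salience Network	SN_R_Lat	3	3
TPN	38	Left Anterior Ventral Lateral Prefrontal Cortex	avlPFC_L	3	3
TPN	39	Right Anterior Ventral Lateral Prefrontal Cortex	avlPFC_R	3	3
TPN	40	Left Posterior Ventral Lateral Prefrontal Cortex	pvlPFC_L	3	3
TPN	41	Right Posterior Ventral Lateral Prefrontal Cortex	pvlPFC_R	3	3
TNN	42	Left Lateral Posterior Default Mode Network	pDMN_L_Lat	4	3
TNN	43	Left Medial Posterior Default Mode Network	pDMN_L_Med	4	4
TNN	44	Right Lateral Posterior Default Mode Network	pDMN_R_Lat	4	3
TNN	45	Right Medial Posterior Default Mode Network	pDMN_R_Med	4	4
TNN	46	Left Lateral Dorsal Default Mode Network	dDMN_L_Lat	4	3
TNN	47	Left Medial Dorsal Default Mode Network	dDMN_L_Med	4	4
TNN	48	Right Lateral Dorsal Default Mode Network	dDMN_R_Lat	4	3
TNN	49	Right Medial Dorsal Default Mode Network	dDMN_R_Med	4	4
TNN	50	Left Lateral Ventral Default Mode Network	vDMN_L_Lat	4	4
TNN	51	Left Medial Ventral Default Mode Network	vDMN_L_Med	4	4
TNN	52	Right Lateral Ventral Default Mode Network	vDMN_R_Lat	4	4
TNN	53	Right Medial Ventral Default Mode Network	vDMN_R_Med	4	4
TNN	54	Left Anterior Dorsal Default Mode Network	adDMN_L	4	4
TNN	55	Right Anterior Dorsal Default Mode Network	adDMN_R	4	4
TNN	56	Left Anterior Ventral Default Mode Network	avDMN_L	4	4
TNN	57	Right Anterior Ventral Default Mode Network	avDMN_R	4	4
TNN	58	Left Cingulate	Cing_L	4	4
TNN	59	Right Cingulate	Cing_R	4	4
TNN	60	Supplementary Motor Area of Language Network	Lang_SMA	4	4
VIS	61	Left Central Primary Visual	cPV_L	5	5
VIS	62	Right Central Primary Visual	cPV_R	5	5
VIS	63	Left Peripheral Primary Visual	pPV_L	5	5
VIS	64	Right Peripheral Primary Visual	pPV_R	5	5
VIS	65	Left Lingual	Ling_L	5	5
VIS	66	Right Lingual	Ling_R	5	5
VIS	67	Left Ventral Visual Stream	VVS_L	5	5
VIS	68	Right Ventral Visual Stream	VVS_R	5	5
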