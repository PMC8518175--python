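gene	cds_accession	protein_accession	locus	scaffold	strand	orf_bp	protein_aa	mw_da	pi	n_exons
DzCAMTA1	XM_022870778.1	XP_022726513.1	LOC111282620	NW_019168048.1	+	2676	891	99995.47	6.74	12
DzCAMTA2	XM_022884479.1	XP_022740214.1	LOC111292222	NW_019168470.1	+	3252	1083	122683.04	6.06	13
DzCAMTA3	XM_022888585.1	XP_022744320.1	LOC111295185	NW_019167849.1	+	3249	1082	121828.47	5.8	13
DzCAMTA4	XM_022895339.1	XP_022751074.1	LOC111299855	NW_019167860.1	+	3153	1050	119054.19	5.71	12
DzCAMTA5	XM_022907953.1	XP_022763688.1	LOC111309099	NW_019167915.1	-	3111	1036	116782.75	5.64	13
DzCAMTA6	XM_022869391.1	XP_022725126.1	LOC111281753	NW_019168048.1	+	2958	985	109475.52	5.56	12
DzCAMTA7	XM_022920611.1	XP_022776346.1	LOC111318006	NW_019167971.1	-	3252	1083	120256.18	5.39	12
DzCAMTA8	XM_022905033.1	XP_022760768.1	LOC111306973	NW_019167904.1	-	3006	1001	111703.91	7.21	12
DzCAMTA9	XM_022866124.1	XP_022721859.1	LOC111279200	NW_019168026.1	-	2745	914	103362.48	7.85	13
DzCAMTA10	XM_022904915.1	XP_022760650.1	LOC111306911	NW_019167904.1	+	2745	914	102912.3	8.1	13
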