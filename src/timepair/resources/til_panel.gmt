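B_cells	B-lymphocyte markers	BLK	CD19	MS4A1	TNFRSF17	TCL1A	SPIB
CD45	pan-leukocyte markers (companions of PTPRC)	PTPRCAP	CD52	LAPTM5	CD48
CD8_T_cells	CD8 T-cell markers	CD8A	CD8B	GZMK
Cytotoxic_cells	cytotoxicity effectors	PRF1	GZMA	GZMB	GZMH	KLRK1	NKG7	GNLY
Dendritic_cells	dendritic-cell markers	CCL13	CD209	HSD11B1
Exhausted_CD8	exhausted CD8 T-cell markers	LAG3	CD244	EOMES	PTGER4
Macrophages	macrophage markers	CD68	CD84	CD163	MS4A4A
Mast_cells	mast-cell markers	TPSAB1	TPSB2	CPA3	MS4A2	HDC
Neutrophils	neutrophil markers	FPR1	FCGR3B	CSF3R	S100A12	CEACAM3
NK_CD56dim	CD56dim NK-cell markers	KIR2DL3	KIR3DL1	KIR3DL2	IL21R
NK_cells	NK-cell markers	NCR1	XCL1	XCL2	KLRD1
T_cells	pan-T-cell markers	CD3D	CD3E	CD3G	CD6	SH2D1A	TRAT1
Th1_cells	Th1 markers	TBX21	IFNG	IL12RB2	STAT4
Treg	regulatory T-cell markers	FOXP3	IL2RA	IKZF2
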