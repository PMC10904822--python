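adhesion_molecules	leukocyte adhesion molecules	ICAM1	VCAM1	ITGB2	SELL	ALCAM
chemokines	lymphocyte-recruiting chemokines	CXCL9	CXCL10	CXCL11	CCL2	CCL5	CCL19
cytolytic_activity	cytolytic effectors	GZMA	PRF1
immunocostimulators	costimulatory receptors and ligands	CD27	CD28	CD40	CD80	CD86	ICOS	TNFRSF9
immunoinhibitors	inhibitory checkpoints	CTLA4	PDCD1	CD274	HAVCR2	BTLA	TIGIT
MHC_class_I	classical class-I antigen presentation	HLA-A	HLA-B	HLA-C	B2M	TAP1	TAP2
MHC_class_II	class-II antigen presentation	HLA-DRA	HLA-DRB1	HLA-DPA1	HLA-DPB1	HLA-DQA1
non_class	non-classical MHC and stress ligands	HLA-E	HLA-F	HLA-G	MICA	MICB
IFNg_signature	interferon-gamma response	STAT1	IDO1	CCR5	CXCL13	IL2RG	PRKCD
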