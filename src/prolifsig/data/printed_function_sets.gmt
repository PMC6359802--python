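proliferation	10-gene cell-cycle signature	BUB1	CCNB2	CDK1	CDKN3	FOXM1	KIAA0101	MAD2L1	MELK	MKI67	TOP2A
antigen_processing	MHC class I/II antigen presentation machinery	CD74	HLA-A	HLA-B	HLA-C	HLA-DMA	HLA-DMB	HLA-DOA	HLA-DOB	HLA-DPA1	HLA-DPB1	HLA-DQA1	HLA-DQA2	HLA-DQB2	HLA-DRA	HLA-DRB1	HLA-E	HLA-F	HLA-F-AS1	HLA-G
dendritic_cell	dendritic-cell markers	HERC6	IL3RA	ITGAX	NRP1	TLR3	ZBTB46
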