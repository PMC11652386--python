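snp_id	gene	ref_allele	alt_allele	case_ref_hom	case_het	case_alt_hom	ctrl_ref_hom	ctrl_het	ctrl_alt_hom
rs2071287	NOTCH4	G	A	81	96	33	83	100	27
rs204993	NOTCH4	T	C	60	102	48	89	100	21
rs2070673	CYP2E1	A	T	46	115	49	31	94	85
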