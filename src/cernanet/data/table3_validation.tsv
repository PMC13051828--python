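pathway	amo1_kd_nes	amo1_kd_fdr	h929_kd_nes	h929_kd_fdr	lp1_kd_nes	lp1_kd_fdr	kms27_kd_nes	kms27_kd_fdr	amo1_ovx_nes	amo1_ovx_fdr	commpass_nes	commpass_fdr
RHO GTPase effectors	-1.80	0.01			-1.92	0.00	-2.78	0.00	3.35	0.00	2.19	0.02
Cell cycle	-2.15	0.01			-1.91	0.00	-2.20	0.00	2.78	0.00	2.05	0.03
Cellular senescence	-1.66	0.03			-2.16	0.00	-2.06	0.01	3.34	0.00	2.06	0.02
VEGFR2 mediated cell proliferation	-1.96	0.03			-1.92	0.03
Opioid signalling	-2.14	0.01			-2.14	0.00
DAG and IP3 signalling	-1.91	0.02			-1.96	0.01
Tight junction	-1.88	0.03			-1.73	0.04
Regulation of actin cytoskeleton	-1.71	0.03			-1.59	0.05
Mitotic spindle	-1.99	0.00			-1.55	0.01			2.36	0.00	2.46	0.00
E2F targets	-2.40	0.00			-2.13	0.00			2.08	0.01
Haemostasis									2.01	0.00	1.71	0.10
Signalling by VEGF											1.82	0.06
Transmission across chemical synapses					-1.55	0.04
Vascular smooth muscle contraction					-1.70	0.05
Calcium signalling pathway					-1.72	0.04
Axon guidance					-1.74	0.04					2.03	0.03
Signalling by receptor tyrosine kinases											1.87	0.05
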