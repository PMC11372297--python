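patient_id	mmr_gene	histology	atrx_loss	p53_staining	pdl1_score	cd8_infiltrate
1	PMS2	GBM IDH-wt (with few giant multi-nucleated cells)	1	1	1	1
4B	MSH6	GBM IDH-wt (with few giant multi-nucleated cells)	1	1	2	1
4A	MSH6	GBM IDH-wt (with few giant multi-nucleated cells)	1	1	0	1
5	PMS2	GBM (with few giant multi-nucleated cells)	1	1	0	1
11	MSH6	GBM (with few giant multi-nucleated cells)	0	1	1	0
14	PMS2	GBM (without giant cells)	1	1	1	1
19	PMS2	AA, IDH-wt (with giganto-cellular features)	0	1	2	1
23	MSH6	GBM (with few giant multi-nucleated cells)	1	NA	0	0
24	PMS2	GBM (with few giant multi-nucleated cells)	1	1	0	1
26	PMS2	AA IDH-wt	1	0	0	0
30	MSH6	GBM	NA	NA	NA	NA
31	PMS2	GBM (with few giant multi-nucleated cells)	1	1	1	0
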