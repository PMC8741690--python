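snp_id	chrom	pos	risk_allele	other_allele	weight
rs9185424	6	32600000	A	G	0.9
rs2743117	22	33868712	C	T	0.42
rs1788133	12	107260385	G	A	0.413
rs1620706	17	67251144	T	C	0.406
rs1266602	13	53980265	A	C	0.399
rs3268410	4	120114231	G	T	0.391
rs3505802	12	38725782	A	G	0.384
rs1856735	21	45078567	C	T	0.377
rs8502747	22	3642604	G	A	0.37
rs2018164	22	14618263	T	C	0.363
rs3546057	14	41637101	A	C	0.356
rs3525272	7	91247132	G	T	0.349
rs6068514	13	47157472	A	G	0.341
rs6332646	15	14106094	C	T	0.334
rs4889752	7	8153480	G	A	0.327
rs4089002	22	1049752	T	C	0.32
rs6997414	13	6509621	A	C	0.313
rs8000642	8	22429318	G	T	0.306
rs5185343	11	134889599	A	G	0.299
rs9688468	3	38623501	C	T	0.291
rs7915634	14	70151125	G	A	0.284
rs3986559	8	109037279	T	C	0.277
rs9640281	21	11552959	A	C	0.27
rs3126556	7	45593508	G	T	0.263
rs7218522	6	74506136	A	G	0.256
rs7190481	14	28903189	C	T	0.249
rs3762216	7	154921418	G	A	0.241
rs6153991	8	26591898	T	C	0.234
rs4118500	9	123981832	A	C	0.227
rs7926013	16	71994306	G	T	0.22
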