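snp_id	case_freq	background_freq
rs9185424	0.99	0.55
rs2743117	0.8953	0.6918
rs1788133	0.8865	0.685
rs1620706	0.8777	0.6782
rs1266602	0.869	0.6714
rs3268410	0.8602	0.6647
rs3505802	0.0278	0.0125
rs1856735	0.027	0.0122
rs8502747	0.0261	0.0117
rs2018164	0.0253	0.0114
rs3546057	0.0245	0.011
rs3525272	0.0236	0.0106
rs6068514	0.0228	0.0103
rs6332646	0.022	0.0099
rs4889752	0.0212	0.0095
rs4089002	0.0203	0.0091
rs6997414	0.0195	0.0088
rs8000642	0.0187	0.0084
rs5185343	0.0178	0.008
rs9688468	0.017	0.0076
rs7915634	0.0162	0.0073
rs3986559	0.0153	0.0069
rs9640281	0.0145	0.0065
rs3126556	0.0137	0.0062
rs7218522	0.0128	0.0058
rs7190481	0.012	0.0054
rs3762216	0.0112	0.005
rs6153991	0.0104	0.0047
rs4118500	0.0095	0.0043
rs7926013	0.0087	0.0039
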