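variant_id	position	major_allele	minor_allele	maf	phenotype	code	n_cases	or	ci_low	ci_high	p
rs2228145	154426970	A	C	0.4094	Asthma	J45	28628	1.003	1.002	1.004	1.29e-6
rs2228145	154426970	A	C	0.4094	Eczema/dermatitis		11552	1.002	1.001	1.003	7.96e-9
rs2228145	154426970	A	C	0.4094	Other dermatitis	L30	1654	1.001	1.000	1.001	5.26e-6
rs2228145	154426970	A	C	0.4094	Monocyte percentage		14307	1.040	1.032	1.048	1.09e-24
rs2228145	154426970	A	C	0.4094	Monocyte count		14322	1.003	1.002	1.003	2.66e-19
rs2228145	154426970	A	C	0.4094	Mean corpuscular hemoglobin		13433	1.024	1.018	1.030	2.19e-16
rs2228145	154426970	A	C	0.4094	Mean corpuscular volume		13219	1.060	1.045	1.075	1.07e-15
rs2228145	154426970	A	C	0.4094	Mean platelet (thrombocyte) volume		13220	0.988	0.985	0.991	9.81e-14
rs2228145	154426970	A	C	0.4094	Platelet count		13258	1.761	1.467	2.113	1.21e-9
rs2228145	154426970	A	C	0.4094	Red blood cell (erythrocyte) distribution width		13429	0.991	0.988	0.994	1.30e-7
rs2228145	154426970	A	C	0.4094	Hemoglobin concentration		13226	1.009	1.005	1.012	4.85e-7
rs2228145	154426970	A	C	0.4094	Platelet distribution width		13220	0.996	0.994	0.998	2.10e-6
rs2228145	154426970	A	C	0.4094	Lymphocyte count		14209	0.995	0.993	0.997	4.39e-6
rs2228145	154426970	A	C	0.4094	Mean sphered cell volume		20355	0.961	0.945	0.978	6.01e-6
rs4845625	154422067	C	T	0.4221	Mean platelet (thrombocyte) volume		13220	1.011	1.008	1.015	2.79e-12
rs4845625	154422067	C	T	0.4221	Platelet count		13258	0.570	0.475	0.685	1.62e-9
rs4845625	154422067	C	T	0.4221	Mean corpuscular hemoglobin		13433	0.986	0.980	0.992	1.63e-6
rs4845625	154422067	C	T	0.4221	Monocyte count		14322	0.999	0.998	0.999	6.08e-6
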