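variant_id	major_allele	minor_allele	maf	outcome	outcome_kind	datasets	n_cases	n_controls	n_total	or	ci_low	ci_high	p	i2	het_p	venice	fprp	cumulative
rs7529229	T	C	0.3535	Coronary heart disease	disease	36	26310	101971		0.954	0.932	0.977	1.07e-4	0.0	0.686	AAA	0.002	Strong
rs7529229	T	C	0.3535	Abdominal aortic aneurysms	disease	5	4529	15734		0.841	0.800	0.884	1.38e-11	8.6	0.322	AAA	<0.001	Strong
rs7529229	T	C	0.3535	Atrial fibrillation	disease	5	2728	16702		0.900	0.850	0.960	0.001	NA		B-C	0.026	Weak
rs4845625	C	T	0.4495	Coronary artery disease	disease	47	63434	110256		1.060	1.042	1.079	1.12e-10	15.7	0.180	AAA	<0.001	Strong
rs4845625	C	T	0.4495	Atrial fibrillation	disease	7	2991	20101		1.179	1.044	1.330	0.007	52.4	0.122	ACA	0.187	Weak
rs4537545	C	T	0.3535	Coronary heart disease	disease	8	13370	30425		0.940	0.903	0.978	0.002	27.7	0.207	ABC	0.040	Moderate
rs4537545	C	T	0.3535	Atrial fibrillation	disease	5	2728	16702		0.901	0.847	0.952	2.32e-4	NA		B-C	0.004	Moderate
rs4129267	C	T	0.3485	Abdominal aortic aneurysms	disease	7	10204	107766		1.141	1.101	1.183	4.83e-13	0.0	0.655	AAA	<0.001	Strong
rs4129267	C	T	0.3485	Asthma	disease	7	62596	389460		1.073	1.035	1.112	1.18e-4	61.1	0.017	AAA	<0.001	Strong
rs28638007	T	C	0.3956	Atrial fibrillation	disease	5	2728	16702		0.900	0.850	0.950	1.07e-4	NA		B-C	0.003	Moderate
rs2228145	A	C	0.3485	Aneurysm	disease	5	27819	352035		0.881	0.851	0.912	8.68e-13	71.4	0.007	AAA	<0.001	Strong
rs2228145	A	C	0.3485	Atherosclerosis	disease	4	91520	327474		0.929	0.908	0.951	6.02e-10	63.9	0.040	AAA	<0.001	Strong
rs2228145	A	C	0.3485	Coronary heart disease	disease	5	204050	1033873		0.957	0.948	0.967	3.17e-17	0.0	0.212	AAA	<0.001	Strong
rs2228145	A	C	0.3485	Crohn's disease	disease	3	32880	70025		0.946	0.927	0.964	2.14e-8	0.0	0.950	AAA	<0.001	Strong
rs2228145	A	C	0.3485	Dermatitis	disease	5	141581	326743		1.048	1.026	1.071	2.31e-5	77.0	0.002	AAA	<0.001	Strong
rs2228145	A	C	0.3485	Asthma	disease	5	28762	105138		1.053	1.023	1.084	4.86e-4	2.9	0.390	AAA	0.009	Strong
rs2228145	A	C	0.3485	Ulcerative colitis	disease	3	30076	75562		0.977	0.957	0.996	0.018	0.0	0.672	AAA	0.254	Moderate
rs2228145	A	C	0.3485	Rheumatoid arthritis	disease	6	18830	51755		0.790	0.693	0.901	4.48e-4	88.0	0.000	AAA	0.004	Strong
rs2228145	A	C	0.3485	Type 1 diabetes	disease	4	38522	780577		0.940	0.898	0.984	0.009	70.1	0.018	AAA	0.234	Moderate
rs2228145	A	C	0.3485	Type 2 diabetes	disease	5	276906	1441968		0.975	0.952	0.998	0.033	34.1	0.194	AAA	0.388	Moderate
rs2228145	A	C	0.3485	Cardiovascular disease	disease	4	2335	35900		0.726	0.535	0.983	0.040	80.2	0.002	BCC	0.796	Weak
rs2228145	A	C	0.3485	Obesity	disease	3	1007	402		1.084	0.796	1.476	0.609	52.0	0.124
rs2228145	A	C	0.3485	Dengue	disease	4	680	850		0.837	0.494	1.417	0.507	73.4	0.010
rs2228145	A	C	0.3485	Mental disorder	disease	7	1845	8481		1.051	0.908	1.216	0.505	38.1	0.138
rs2228145	A	C	0.3485	Multiple myeloma	disease	4	958	433		1.129	0.791	1.610	0.505	64.8	0.036
rs2228145	A	C	0.3485	COPD	disease	6	7519	35653		1.019	0.965	1.076	0.497	0.0	0.850
rs2228145	A	C	0.3485	Anterior cruciate ligament injury	disease	3	406	411		0.937	0.735	1.194	0.597	21.9	0.278
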