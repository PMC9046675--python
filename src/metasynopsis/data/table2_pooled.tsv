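variant_id	major_allele	minor_allele	maf	outcome	outcome_kind	datasets	n_cases	n_controls	n_total	or	ci_low	ci_high	p	i2	het_p	venice	fprp	cumulative
rs7529229	T	C	0.3535	CRP level	categorical_phenotype	5			86998	0.913	0.904	0.921	2.58e-81	0.0	0.779	AAA	<0.001	Strong
rs7529229	T	C	0.3535	IL-6 level	categorical_phenotype	3			38194	1.089	1.076	1.102	3.88e-46	39.7	0.191	AAA	<0.001	Strong
rs7529229	T	C	0.3535	Fibrinogen level	categorical_phenotype	8			82958	0.976	0.947	1.006	0.121	90.1	<0.001
rs7518199	A	C	0.3600	Fibrinogen level	categorical_phenotype	6			23634	0.953	0.936	0.971	2.75e-7	35.5		AAA	<0.001	Strong
rs7518199	A	C	0.3600	IL-6 level	categorical_phenotype	3			12546	1.090	1.061	1.121	8.79e-10	80.0	0.007	AAA	<0.001	Strong
rs6667434	G	A	0.4293	CRP level	categorical_phenotype	4			10471	0.921	0.897	0.946	1.06e-9	0.0	0.967	AAA	<0.001	Strong
rs4845371	C	T	0.4293	CRP level	categorical_phenotype	4			10471	0.921	0.897	0.946	1.06e-9	0.0	0.967	AAA	<0.001	Strong
rs4845625	C	T	0.4495	CRP level	categorical_phenotype	3			8724	1.088	1.058	1.117	1.45e-9	0.0	0.371	AAC	<0.001	Moderate
rs4845618	T	G	0.4394	IL-6 level	categorical_phenotype	3			12546	0.941	0.927	0.955	8.98e-16	31.4	0.233	AAA	<0.001	Strong
rs4553185	T	C	0.4343	IL-6 level	categorical_phenotype	3			12546	0.936	0.919	0.953	6.04e-4	52.5	0.122	AAA	<0.001	Strong
rs4537545	C	T	0.3535	CRP level	categorical_phenotype	8			103289	0.916	0.882	0.952	9.00e-6	91.8	<0.001	AAA	<0.001	Strong
rs4537545	C	T	0.3535	Fibrinogen level	categorical_phenotype	7			41320	0.949	0.933	0.966	3.03e-9	0.0	0.409	AAA	<0.001	Strong
rs4537545	C	T	0.3535	IL-6 level	categorical_phenotype	3			12546	1.098	1.071	1.126	3.10e-13	76.0	0.015	AAA	<0.001	Strong
rs4537545	C	T	0.3535	LDL cholesterol level	categorical_phenotype	4			16251	1.080	0.728	1.603	0.702	0.0	0.862
rs4537545	C	T	0.3535	Total cholesterol level	categorical_phenotype	4			16251	0.977	0.694	1.375	0.893	0.0	0.887
rs4537545	C	T	0.3535	Triglyceride level	categorical_phenotype	3			15256	0.973	0.879	1.077	0.601	28.1	0.249
rs4129267	C	T	0.3485	CRP level	categorical_phenotype	14			358529	0.915	0.903	0.927	6.71e-43	59.1	0.003	AAA	<0.001	Strong
rs4129267	C	T	0.3485	Fibrinogen level	categorical_phenotype	7			41320	0.951	0.933	0.969	1.70e-7	6.1	0.302	AAA	<0.001	Strong
rs4129267	C	T	0.3485	IL-6 level	categorical_phenotype	3			14271	1.093	1.074	1.113	7.97e-18	48.3	0.145	ABA	<0.001	Strong
rs4129267	C	T	0.3485	IL-6R level	categorical_phenotype	3			911	1.271	1.061	1.523	0.009	95.0	<0.001	BCC	0.4000	Weak
rs2228145	A	C	0.3485	CRP level	categorical_phenotype	14			483500	0.909	0.893	0.925	3.32e-26	68.6	<0.001	AAA	<0.001	Strong
rs2228145	A	C	0.3485	sIL-6R level	categorical_phenotype	6			8149	1.346	1.318	1.374	4.66e-171	54.6	0.051	ABA	<0.001	Strong
rs2228145	A	C	0.3485	IL-6 level	categorical_phenotype	5			42267	1.130	1.088	1.174	3.17e-10	89.6	<0.001	AAA	<0.001	Strong
rs2228145	A	C	0.3485	Fibrinogen level	categorical_phenotype	9			98330	0.960	0.931	0.990	0.009	87.8	<0.001	AAA	0.150	Moderate
rs2228145	A	C	0.3485	LDL cholesterol level	categorical_phenotype	3			81202	1.000	0.996	1.003	0.857	0.0	0.708
rs2228145	A	C	0.3485	HDL cholesterol level	categorical_phenotype	5			97754	1.076	0.860	1.347	0.520	62.1	0.032
rs2228145	A	C	0.3485	Triglyceride level	categorical_phenotype	5			96257	1.067	0.855	1.332	0.568	59.0	0.045
rs2228145	A	C	0.3485	Systolic blood pressure	categorical_phenotype	3			100502	0.894	0.713	1.120	0.329	44.6	0.165
rs2228145	A	C	0.3485	Fasting glucose	categorical_phenotype	4			185044	1.000	0.998	1.003	0.799	0.0	0.668
rs2228145	A	C	0.3485	Waist circumference	categorical_phenotype	3			69772	1.002	0.998	1.005	0.283	46.7	0.131
rs2228145	A	C	0.3485	BMI	categorical_phenotype	4			895213	1.001	0.998	1.004	0.383	40.7	0.168
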