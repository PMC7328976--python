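variant	cancer	significant	or_pooled	ci_low	ci_high	p_value	i_squared_pct	het_p	fprp_category	venice_initial	final_grade
rs16901979	prostate	1	1.456	1.31	1.64	1.12e-11	84.3	0.000	<0.05	weak	moderate
rs1447295	prostate	1	1.29	1.21	1.38	2.74e-14	77.6	0.000	<0.05	weak	moderate
DG8S737 -8	prostate	1	1.29	1.12	1.48	2.83e-4	2.32	0.803	<0.05	strong	strong
rs6983561	prostate	1	1.29	1.02	1.64	0.04	92.2	0.000	>0.20	weak	weak
rs10090154	prostate	1	1.33	1.17	1.52	1.87e-5	0.0	0.873	<0.05	strong	strong
rs7000448	prostate	1	1.11	1.04	1.19	0.003	36.2	0.152	<0.05	moderate	strong
rs13254738	prostate	1	1.11	1.01	1.22	0.026	59.8	0.029	0.05–0.20	weak	weak
rs6983267	prostate	1	1.14	1.04	1.25	0.006	90.5	0.000	<0.05	weak	moderate
rs7017300	prostate	1	1.39	1.15	1.68	0.001	83.3	0.000	<0.05	weak	moderate
rs7837688	prostate	1	1.48	1.29	1.71	4.76e-8	80.1	0.000	<0.05	weak	moderate
rs1016343	prostate	1	1.33	1.20	1.48	5.64e-8	70.2	0.009	<0.05	weak	moderate
rs7008482	prostate	1	0.77	0.62	0.96	0.021	69.2	0.039	>0.20	weak	weak
rs4242384	prostate	1	1.42	1.05	1.92	0.022	81.3	0.005	0.05–0.20	weak	weak
rs620861	prostate	1	0.84	0.77	0.92	7.49e-5	73.1	0.005	<0.05	weak	moderate
rs10086908	prostate	1	0.73	0.60	0.88	0.001	89.3	0.000	<0.05	weak	moderate
rs10505477	colorectal	1	1.13	1.09	1.18	7.03e-11	29.2	0.185	<0.05	weak	moderate
rs6983267	colorectal	1	1.17	1.08	1.19	4.66e-7	64.4	0.000	<0.05	weak	moderate
rs10808556	colorectal	1	1.18	1.12	1.25	2.10e-9	0.0	0.394	<0.05	strong	strong
rs6983267	thyroid	1	1.19	1.08	1.31	3.57e-4	78.6	0.000	<0.05	weak	moderate
rs55705857	glioma	1	3.54	2.90	4.33	2.31e-35	10.9	0.326	<0.05	strong	strong
rs13281615	breast	1	1.13	1.08	1.18	3.98e-7	58.9	0.007	<0.05	weak	moderate
rs9642880	bladder	1	1.25	1.20	1.30	1.79e-27	4.10	0.39	<0.05	strong	strong
rs1447295	stomach	1	0.80	0.65	0.99	0.035	28.0	0.249	0.05–0.20	moderate	moderate
rs4242382	prostate	0
rs4645959	prostate	0
rs7837328	prostate	0
rs16901966	prostate	0
rs10505476	prostate	0
rs13281615	prostate	0
rs1447295	colorectal	0
rs7837328	colorectal	0
rs10090154	colorectal	0
rs4295627	glioma	0
rs1562430	breast	0
rs6983267	breast	0
rs6983267	stomach	0
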