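anesthetic	site	conformation	dG_solv	dG_sym	dG_V	dG_bind1	dG_bind1_err	dG_bind2	dG_bind2_err	kd1_uM	kd2_uM	ic50_range_uM	exp_ic50_uM
isoflurane	pore	closed	-0.2	0.0	-0.3	-7.6	0.2	-5.6	0.4	2.9	83	2.8-86	60
isoflurane	pore	open	-0.2	0.0	-0.3	-4.4	0.9	-4.5	0.7	620	530	370-890	60
isoflurane	allosteric	NA	-0.2	0.0	-0.7	-3.5	0.3	NA	NA	2800	NA	NA	NA
propofol	pore	closed	-1.5	0.4	-0.3	-8.7	0.2	-7.9	0.9	0.46	1.8	0.38-2.1	24
propofol	pore	open	-1.5	0.4	-0.3	-8.0	0.6	-7.6	1.2	1.5	2.9	1.1-4.0	24
propofol	allosteric	NA	-1.5	0.4	-0.7	-6.9	0.2	NA	NA	9.4	NA	NA	NA
ethanol	pore	closed	-4.6	0.4	-0.3	-0.2	0.3	NA	NA	510000	NA	NA	NA
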