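# Fluorescence lifetime components of coupled disk assemblies and controls
# (465 nm excitation, 524 nm emission; +/- asymptotic standard errors).
sample	label	tau_long_ns	se_long	tau_short_ns	se_short	short_amp_pct
1	OG488 alone (Mesna capped)	4.11	0.02
2	donor disk sparsely labeled with OG488	4.79	0.02	2.0	0.2	11.52
3	donor disk quantitatively labeled with OG488	4.52	0.02	1.79	0.09	21.50
4	donor disk quantitatively labeled, coupled to 4-methylcatechol	4.36	0.02	1.37	0.07	28.69
5	donor disk quantitatively labeled, coupled to unlabeled acceptor disk	4.52	0.02	1.7	0.1	15.69
6	donor disk quantitatively labeled, mixed with labeled acceptor disk	4.54	0.02	1.5	0.2	9.92
7	donor disk quantitatively labeled, coupled to labeled acceptor disk	4.39	0.02	0.86	0.05	35.82
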