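index	AA	AC	AG	AU	CA	CC	CG	CU	GA	GC	GG	GU	UA	UC	UG	UU
stacking_free_energy_dG37	-0.93	-2.24	-2.08	-1.10	-2.11	-3.26	-2.36	-2.08	-2.35	-3.42	-3.26	-2.24	-1.33	-2.35	-2.11	-0.93
stacking_enthalpy_dH	-6.82	-11.40	-10.48	-9.38	-10.44	-13.39	-10.64	-10.48	-12.44	-14.88	-13.39	-11.40	-7.69	-12.44	-10.44	-6.82
stacking_entropy_dS	-19.0	-29.5	-27.1	-26.7	-26.9	-32.7	-26.7	-27.1	-32.5	-36.9	-32.7	-29.5	-20.5	-32.5	-26.9	-19.0
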