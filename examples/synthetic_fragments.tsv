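label	part	electrostatics	exchange	induction	dispersion	total	n_heavy_atoms
Y210	side_chain	-8.58	9.2	-3.15	-10.35	-12.88	8
F154	backbone_amide	-5.5	2.1	-1.3	-5.15	-9.85	5
A120	backbone_amide	-5.37	2.4	-1.3	-4.5	-8.77	5
W199	backbone_amide	-3.72	1.6	-0.92	-1.76	-4.8	5
W199	side_chain	-4.3	3.1	-0.33	-5.2	-6.73	10
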