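label	q_ct	bond_class
Y210:O(H-Nsp2)	0.0125	classical_hbond
W213:N(H-Nsp2)	0.05	classical_hbond
A120:(O-H)Csp3	0.005	nonclassical_hbond
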