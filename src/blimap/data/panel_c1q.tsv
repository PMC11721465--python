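variant	ligand	KD	KD_unit	class
WT	C1q	0.65	uM	binding
M41D	C1q	2.54	uM	binding
L69D	C1q		uM	decreased_binding
W70D	C1q		uM	decreased_binding
L71D	C1q	0.058	uM	binding
F74D	C1q	0.11	uM	binding
L89D	C1q		uM	decreased_binding
L69D/L71D	C1q		uM	binding (not fit)
W44D/L69D/L71D	C1q		uM	binding (not fit)
R46A/R47A	C1q		uM	no_binding_detected
R46A	C1q		uM	no_binding_detected
R46D	C1q		uM	no_binding_detected
R47H	C1q	0.18	uM	binding
R62H	C1q	1.66	uM	binding
R76D	C1q	13.8	uM	binding
R77D	C1q		uM	no_binding_detected
T96K	C1q		uM	no_binding_detected
L75D	C1q	0.11	uM	binding
T85D	C1q	0.11	uM	binding
R122D/K123D	C1q	0.82	uM	binding
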