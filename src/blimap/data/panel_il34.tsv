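variant	ligand	KD	KD_unit	class
WT	IL-34	16.5	nM	binding
R47H	IL-34	79.8	nM	binding
R62H	IL-34	75	nM	binding
D87N	IL-34	28.4	nM	binding
T96K	IL-34	23.7	nM	binding
R46D	IL-34	18.0	nM	binding
R76D	IL-34		nM	no_binding_detected
R77D	IL-34	114	nM	binding
L75D	IL-34	36.6	nM	binding
W78D	IL-34	17.2	nM	binding
T85D	IL-34	21.5	nM	binding
R122E	IL-34	29.4	nM	binding
R122D/K123D	IL-34	18.5	nM	binding
L69D/L71D	IL-34	20.2	nM	binding
W44D/L69D/L71D	IL-34	25.8	nM	binding
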