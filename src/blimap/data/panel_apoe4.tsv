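variant	ligand	KD	KD_unit	class
WT	apoE4	281	nM	binding
R47H	apoE4	643	nM	binding
R62H	apoE4	561	nM	binding
D87N	apoE4	25	nM	binding
T96K	apoE4	891	nM	binding
M41D	apoE4	1426	nM	binding
W44D	apoE4	2565	nM	binding
L69D	apoE4	55060	nM	binding
W70D	apoE4	28110	nM	binding
F74D	apoE4	9709	nM	binding
L69D/L71D	apoE4		nM	no_binding_detected
W44D/L69D/L71D	apoE4		nM	no_binding_detected
R76D	apoE4	1529	nM	binding
R77D	apoE4	1659	nM	binding
R46A/R47A	apoE4	388	nM	binding
R122D/K123D	apoE4	120	nM	binding
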