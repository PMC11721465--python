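variant	ligand	KD	KD_unit	class
WT	TDP-43		uM	binding
R46A/R47A	TDP-43		uM	decreased_binding
L69D/L71D	TDP-43		uM	no_binding_detected
W44D/L69D/L71D	TDP-43		uM	no_binding_detected
W70D	TDP-43		uM	no_binding_detected
R62H	TDP-43		uM	binding
D87N	TDP-43		uM	binding
R47H	TDP-43		uM	binding
R122D/K123D	TDP-43		uM	binding
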