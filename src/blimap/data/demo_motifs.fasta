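>demo_motif planted complementary-hydropathy motif (plant position 31 in demo_target)
CHVCAAKQ
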