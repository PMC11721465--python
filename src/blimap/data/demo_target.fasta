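>demo_target synthetic 80-mer carrying the demo_motif complement at residues 31-38
KRVLNVFFKGMFSYDPRLSYHICSVRPQWYRLGKHQFCENDCGMQDTMVMFVQSRMGNPMGQGSSSSRCNFVACPFCKDY
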