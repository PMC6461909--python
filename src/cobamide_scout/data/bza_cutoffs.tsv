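hmm_name	trusted_cutoff
bzaA	200.0
bzaB	180.0
bzaC	150.0
bzaD	300.0
bzaE	280.0
bzaF	220.0
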