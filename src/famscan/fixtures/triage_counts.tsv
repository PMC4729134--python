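triage_class	count	subset_of
no_domain	42	
nonfunctional	37	
functional	90	
possibly_assembly	15	nonfunctional
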