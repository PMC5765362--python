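species	copy_number	trait
elegans	31	3.3
sp34	12	3.1
briggsae	26	4.9
remanei	22	3.0
angaria	30	4.1
pacificus	13	4.6
suum	4	3.6
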