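accession	subtype
TIGR02547	I-E
TIGR02589	I-C
TIGR02556	I-F
TIGR04329	II-A
TIGR02710	III-A
TIGR02684	III-B
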