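accession	cas_name
COG1518	cas1
TIGR00287	cas1
COG1343	cas2
TIGR01573	cas2
COG3512	cas2-homolog
COG1203	cas3
TIGR01587	cas3
COG1468	cas4
TIGR00372	cas4
COG1688	cas5
TIGR02593	cas5
COG1583	cas6
TIGR01877	cas6
COG1857	cas7
TIGR02590	cas7
COG1857b	cas8
TIGR02577	cas8
COG3513	cas9
TIGR01865	cas9
COG1353	cas10
TIGR02578	cas10
TIGR02221	csx
PF09827	cas2
PF01867	cas1
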