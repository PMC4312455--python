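name	iupac
ERELEE4	AWTTCAAA
TGTCACA-element	TGTCACA
I-box	GATAAG
I-box-core	GATAA
I-box-like	AGATATGATAAAA
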