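individual_id	dataset
DG1	DG
DG2	DG
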