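individual_id	dataset
F1S	JPN
F1T	JPN
F1U	JPN
F2V	JPN
F2W	JPN
F2X	JPN
F2Y	JPN
INA	JPN
INB	JPN
IND	JPN
INE	JPN
INM	JPN
INR	JPN
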