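id	kind	completeness	contamination
MAG12a	MAG	86.9	4.8
MAG19a	MAG	99.4	1.3
MAG22a	MAG	78.4	3.8
MAG26a	MAG	98.9	0.9
MAG27a	MAG	78.5	4.1
MAG32a	MAG	97.1	1.4
MAG33a	MAG	82.5	1.3
MAG2p	MAG	89.8	1.9
MAG14p	MAG	98.7	0.2
MAG15p	MAG	85.9	2.2
MAG16p	MAG	94.9	2.2
MAG17p	MAG	82.4	0.5
MAG18p	MAG	96.7	0.9
MAG38p	MAG	87.7	2.4
MAG39p	MAG	91.0	2.7
MAG47p	MAG	95.7	1.1
MAG49p	MAG	70.7	0.0
PC2	isolate	98.3	0.8
PC3	isolate	97.9	1.7
ANDR5	isolate	99.8	4.1
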