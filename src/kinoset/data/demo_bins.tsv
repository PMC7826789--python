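name	smarts	priority	is_fallback
4-anilino-quinazoline	c1ccc(Nc2ncnc3ccccc23)cc1	1	0
oxindole	O=C1Cc2ccccc2N1	2	0
indazole	c1ccc2[nH]ncc2c1	3	0
7-azaindole	c1cnc2[nH]ccc2c1	4	0
benzimidazole	c1ccc2[nH]cnc2c1	5	0
indole	c1ccc2[nH]ccc2c1	6	0
quinazoline	c1ccc2ncncc2c1	7	0
quinoline	c1ccc2ncccc2c1	8	0
isoquinoline	c1ccc2cnccc2c1	9	0
aminopyrimidine	Nc1ncccn1	10	0
pyrimidine	c1cncnc1	11	0
pyrazole	c1cc[nH]n1	12	0
other		13	1
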