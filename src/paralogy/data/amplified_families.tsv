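family	apple	arabidopsis	poplar	n_young_ks	d_young
20S proteasome alpha/beta subunits	29	23	21	18	11
Chlorophyll a/b-binding proteins	27	21	23	13	14
beta-amylases	18	9	10	10	8
Elongation factor-1	18	5	13	10	8
Malate dehydrogenases	14	12	10	8	6
Glyceraldehyde 3-phosphate dehydrogenase	13	10	10	7	6
alpha-tubulins	11	8	9	4	7
S-adenosylmethionine synthetases	10	4	6	6	4
Vacuolar sorting receptors	8	7	5	3	5
26S proteasome regulatory subunit (RPN8)	5	2	2	2	3
Starch phosphorylases	6	2	4	3	3
40S ribosomal protein S5	6	2	2	1	5
40S ribosomal protein S4	6	3	5	3	3
60S ribosomal protein L12	6	3	3	4	2
ADP-glucose pyrophosphorylase family	5	3	2	3	2
Aconitate hydratases	5	4	4	2	3
GDP-mannose 3,5-epimerase	4	1	2	1	3
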