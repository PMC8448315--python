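order	scaffold+fossils+hpas	fossils+hpas	scaffold+fossils	scaffold+hpas	fossils	hpas	scaffold
Afrosoricida	14	32	18	14	44	40	16
Carnivora	16	32,34	4	2	44,46	32	4
Cetartiodactyla	4	30	8	24	44	42,42	8
Chiroptera	12	36	12	16	44	40	16
Cingulata	0	32	2	0	44	36	0
Dermoptera	2	18	2	2	44	34	2
Eulipotyphla	10	28,28	18,20	14	44	38	18
Hyracoidea	12	34	0	0	44,46	32	0
Lagomorpha	0	20	2	0	46	36	0
Macroscelidea	12,10,14	36,34	4	4	44	34	4
Perissodactyla	0	18	6	4	44	36	4
Pholidota	14	32	12	14	44	34	14
Pilosa	0	32	2	0	44	34	0
Primates	2	20	2	2	44	34	2
Proboscidea	0	30	0	0	48	34,34,34	0
Rodentia	4	22	8	4	46	46,44	4
Scandentia	2	18,20	2	2	44	38	2
Sirenia	0	20	0,2	0	44	34,34,34	0
Tubulidentata	14	32,30,32	6	12	44	34,34	12
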