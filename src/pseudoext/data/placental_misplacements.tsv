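order	scaffold+fossils+hpas	fossils+hpas	scaffold+fossils	scaffold+hpas	fossils	hpas	scaffold
Afrosoricida	1,2	1,2	1,2,4	1,2	1,2,4	1,2	1,2,4
Carnivora	1,2	1,2	1	1	1,2	1,2	1
Cetartiodactyla	5	2,5	4	1,2,4	2,5	1,2,4	4
Chiroptera	1,2,5	1,2,5	1,2,5	1,2,5	1,2,5	1,2,5	1,2,5
Cingulata		3			3	1,2
Dermoptera	1	1	1	1	1,2	1,3	1
Eulipotyphla	1,2	1,2	1,2,4	1,2,5	1,2,4	1,2,5	1,2,4
Hyracoidea	1,2	1,2			1,2	3
Lagomorpha		1			2	1,3
Macroscelidea	1,2	1,2	1	1	1,2	1,3	1
Perissodactyla			1	1	2	1,2	1
Pholidota	1,2	1,2	1,2	1,2	1,2	1,2	1,2
Pilosa		1,2			3	1,2
Primates	1	1	1	1	1,2	1,3	1
Proboscidea		2			2	3
Rodentia	5	2,5	1,4	5	1,2,4	2,5	5
Scandentia	1	1	1	1	1,2	1,3	1
Sirenia					2	3
Tubulidentata	1,2	1,2	1,2	1,2	1,2	1,2	1,2
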