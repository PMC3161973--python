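category	count
Anthocyanin biosynthesis	6
Betalain biosynthesis	4
Brassinosteroid biosynthesis	7
Caffeine metabolism	2
Carotenoid biosynthesis	53
Diterpenoid biosynthesis	37
Flavone and flavonol biosynthesis	11
Flavonoid biosynthesis	34
Glucosinolate biosynthesis	7
Indole alkaloid biosynthesis	27
Isoquinoline alkaloid biosynthesis	29
Limonene and pinene degradation	119
Novobiocin biosynthesis	24
Phenylpropanoid biosynthesis	134
Stilbenoid, diarylheptanoid and gingerol biosynthesis	85
Streptomycin biosynthesis	37
Terpenoid backbone biosynthesis	63
Tetracycline biosynthesis	12
Tropane, piperidine and pyridine alkaloid biosynthesis	22
Zeatin biosynthesis	26
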