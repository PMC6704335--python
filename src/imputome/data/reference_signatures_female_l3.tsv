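group	id	function
Kapha	V262	Ribosome
Kapha	V247	Purine metabolism
Kapha	V85	DNA repair and recombination proteins
Kapha	V248	Pyrimidine metabolism
Kapha	V163	Lipopolysaccharide biosynthesis proteins
Kapha	V162	Lipopolysaccharide biosynthesis
Kapha	V212	Peptidases
Kapha	V64	Chaperones and folding catalysts
Kapha	V68	Chromosome
Kapha	V308	Ubiquinone and other terpenoid-quinone biosynthesis
Kapha	V231	Pores ion channels
Kapha	V54	Carbon fixation pathways in prokaryotes
Kapha	V194	One carbon pool by folate
Kapha	V213	Peptidoglycan biosynthesis
Kapha	V137	Glycosyltransferases
Kapha	V87	DNA replication proteins
Kapha	V119	General function prediction only
Kapha	V144	Homologous recombination
Kapha	V10	Amino acid related enzymes
Kapha	V76	Cysteine and methionine metabolism
Kapha	V112	Folate biosynthesis
Kapha	V233	Prenyltransferases
Kapha	V179	Mismatch repair
Kapha	V86	DNA replication
Kapha	V124	Glutathione metabolism
Kapha	V289	Terpenoid backbone biosynthesis
Kapha	V261	Riboflavin metabolism
Kapha	V298	Translation factors
Kapha	V168	Lysosome
Kapha	V191	Nucleotide excision repair
Kapha	V18	Arachidonic acid metabolism
Kapha	V243	Protein folding and associated processing
Kapha	V133	Glycosphingolipid biosynthesis - ganglio series
Kapha	V293	Toluene degradation
Kapha	V134	Glycosphingolipid biosynthesis - globo series
Kapha	V62	Cellular antigens
Kapha	V91	Drug metabolism - other enzymes
Kapha	V129	Glycine, serine and threonine metabolism
Kapha	V319	Vitamin B6 metabolism
Kapha	V241	Protein digestion and absorption
Kapha	V13	Aminobenzoate degradation
Kapha	V154	Isoquinoline alkaloid biosynthesis
Pitta	V300	Transporters
Pitta	V2	ABC transporters
Pitta	V275	Sporulation
Pitta	V311	Valine, leucine and isoleucine biosynthesis
Pitta	V19	Arginine and proline metabolism
Pitta	V249	Pyruvate metabolism
Pitta	V210	Pentose and glucuronate interconversions
Pitta	V177	Methane metabolism
Pitta	V143	Histidine metabolism
Pitta	V211	Pentose phosphate pathway
Pitta	V138	Glyoxylate and dicarboxylate metabolism
Pitta	V166	Lysine biosynthesis
Pitta	V46	C5-Branched dibasic acid metabolism
Pitta	V127	Glycerolipid metabolism
Pitta	V218	Phenylalanine, tyrosine and tryptophan biosynthesis
Pitta	V128	Glycerophospholipid metabolism
Pitta	V284	Sulfur relay system
Pitta	V290	Tetracycline biosynthesis
Pitta	V205	Pantothenate and CoA biosynthesis
Pitta	V65	Chloroalkane and chloroalkene degradation
Pitta	V244	Protein kinases
Pitta	V198	Other transporters
Pitta	V253	RNA transport
Pitta	V187	Nitrotoluene degradation
Vata	V304	Two-component system
Vata	V23	Bacterial chemotaxis
Vata	V186	Nitrogen metabolism
Vata	V75	Cyanoamino acid metabolism
Vata	V52	Carbohydrate metabolism
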