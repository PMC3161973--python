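stage	raw_total	raw_distinct	clean_total	clean_distinct	all_mapped_total	all_mapped_distinct	unambiguous_total	unambiguous_distinct	all_mapped_genes	unambiguous_mapped_genes	unknown_total	unknown_distinct	reference_gene_count
3DAF	3510563	207988	3382707	87140	1573645	46700	1566698	46520	19607	19492	1809062	40440	43891
50DAF	3738193	202720	3612715	85737	1237119	46865	1233379	46689	21534	21406	2375596	38872	43891
70DAF	3784929	184923	3682563	91130	1379598	51320	1376138	51138	21865	21761	2302965	39810	43891
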