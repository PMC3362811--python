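locus	chrom	start_1based	end_1based	deletion_size	mechanism	microhomology_bp
87	chr1	35413213	35414369	1017	NHEJ	4
273	chr1	181923989	181924621	682	NHEJ	0
361	chr1	249205332	249205990	4980	NHEJ	5
432	chr2	44288699	44288879	277	NHEJ	7
574	chr2	184655950	184658043	113	NHEJ	2
689	chr3	42024110	42025361	4463	NHEJ	2
1505	chr7	55378897	55379920	1271	NHEJ	0
1652	chr8	11186832	11188441	305	NHEJ	3
2299	chr11	3418351	3419320	367	NHEJ	2
2335	chr11	46606606	46606899	526	NHEJ	2
2493	chr12	18672855	18672949	589	NAHR	36
2836	chr15	20408545	20409855	312	NHEJ	4
2981	chr16	30170002	30170483	850	NHEJ	1
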