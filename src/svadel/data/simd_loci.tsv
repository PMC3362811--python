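locus	chrom	start_1based	end_1based	deletion_size
242	chr3	14909866	149099196	2581
732	chr3	61656812	61658447	19
831	chr12	31333177	31333788	347
1547	chr7	75581297	75582629	653
1667	chr22	35021272	35022965	1633
1671	chr14	84565214	84566566	8741
1755	chr8	122668707	122669486	1191
2263	chr8	57983370	57984835	14
2508	chr8	145092008	145092734	4859
2809	chr8	34951832	34952650	2791
2817	chr1	160905975	160906748	1929
3019	chr10	101851975	101854321	5997
3577	chr16	67746159	67746860	30
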