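chrom	bp	cM
chr1	0	0
chr1	105000000	167.1703
chr1	145000000	190.0228
chr1	249250621	356.0000
chr2	0	0
chr2	73300000	110.1981
chr2	113300000	131.7113
chr2	243199373	327.0000
chr3	0	0
chr3	71000000	113.9880
chr3	111000000	136.2885
chr3	198022430	276.0000
chr4	0	0
chr4	30400000	49.7569
chr4	70400000	72.3565
chr4	191154276	270.0000
chr5	0	0
chr5	28400000	46.8475
chr5	68400000	69.3995
chr5	180915260	255.0000
chr6	0	0
chr6	41000000	69.7320
chr6	81000000	92.7341
chr6	171115067	246.0000
chr7	0	0
chr7	39900000	69.8859
chr7	79900000	93.2114
chr7	159138663	232.0000
chr8	0	0
chr8	25600000	47.5906
chr8	65600000	71.8589
chr8	146364022	222.0000
chr9	0	0
chr9	29000000	49.2875
chr9	69000000	71.2684
chr9	141213431	194.0000
chr10	0	0
chr10	20200000	40.6528
chr10	60200000	66.3879
chr10	135534747	218.0000
chr11	0	0
chr11	33700000	60.0335
chr11	73700000	82.7880
chr11	135006516	192.0000
chr12	0	0
chr12	15800000	31.2758
chr12	55800000	56.4977
chr12	133851895	211.0000
chr13	0	0
chr13	1	0.0000
chr13	37900000	20.0080
chr13	115169878	152.0000
chr14	0	0
chr14	1	0.0000
chr14	37600000	20.3149
chr14	107349540	145.0000
chr15	0	0
chr15	1	0.0000
chr15	39000000	23.7352
chr15	102531392	156.0000
chr16	0	0
chr16	16600000	46.1184
chr16	56600000	76.2220
chr16	90354753	170.0000
chr17	0	0
chr17	4000000	13.8777
chr17	44000000	48.9537
chr17	81195210	178.0000
chr18	0	0
chr18	1	0.0000
chr18	37200000	28.5871
chr18	78077248	150.0000
chr19	0	0
chr19	6500000	32.2206
chr19	46500000	67.3979
chr19	59128983	130.0000
chr20	0	0
chr20	7500000	33.2958
chr20	47500000	68.0754
chr20	63025520	137.0000
chr21	0	0
chr21	1	0.0000
chr21	33200000	23.7291
chr21	48129895	86.0000
chr22	0	0
chr22	1	0.0000
chr22	34700000	21.9138
chr22	51304566	81.0000
chrX	0	0
chrX	40600000	56.8657
chrX	80600000	75.4140
chrX	155270560	180.0000
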