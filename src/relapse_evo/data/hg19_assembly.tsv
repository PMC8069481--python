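chrom	length	cen_start	cen_end	is_autosome
chr1	249250621	121535435	124535434	1
chr2	243199373	92326172	95326171	1
chr3	198022430	90504855	93504854	1
chr4	191154276	49660118	52660117	1
chr5	180915260	46405642	49405641	1
chr6	171115067	58830167	61830166	1
chr7	159138663	58054332	61054331	1
chr8	146364022	43838888	46838887	1
chr9	141213431	47367680	50367679	1
chr10	135534747	39254936	42254935	1
chr11	135006516	51644206	54644205	1
chr12	133851895	34856695	37856694	1
chr13	115169878	16000001	19000000	1
chr14	107349540	16000001	19000000	1
chr15	102531392	17000001	20000000	1
chr16	90354753	35335802	38335801	1
chr17	81195210	22263007	25263006	1
chr18	78077248	15460899	18460898	1
chr19	59128983	24681783	27681782	1
chr20	63025520	26369570	29369569	1
chr21	48129895	11288130	14288129	1
chr22	51304566	13000001	16000000	1
chrX	155270560	58632013	61632012	0
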