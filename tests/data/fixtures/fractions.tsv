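# sipscreen output
# bundle: sipscreen-fixture-v1
# seed: 20230211
gradient_id	fraction_index	density	copies
C13_E_coli_1d	1	1.784615385	266887.889
C13_E_coli_1d	2	1.793846154	3817782.5
C13_E_coli_1d	3	1.803076923	25320575.27
C13_E_coli_1d	4	1.812307692	43372214.64
C13_E_coli_1d	5	1.821538462	16379586.88
C13_E_coli_1d	6	1.830769231	3191191.597
C13_E_coli_1d	7	1.84	584575.9325
C13_E_coli_1d	8	1.849230769	1970542.997
C13_E_coli_1d	9	1.858461538	2014411.728
C13_E_coli_1d	10	1.867692308	707646.6038
C13_E_coli_1d	11	1.876923077	95046.53958
C13_E_coli_1d	12	1.886153846	2032.790042
C13_E_coli_1d	13	1.895384615	20.47513177
C12_E_coli_1d	1	1.784615385	198323.3901
C12_E_coli_1d	2	1.793846154	4047007.757
C12_E_coli_1d	3	1.803076923	23291763.94
C12_E_coli_1d	4	1.812307692	47030514.74
C12_E_coli_1d	5	1.821538462	17165755.13
C12_E_coli_1d	6	1.830769231	3189620.671
C12_E_coli_1d	7	1.84	165536.2795
C12_E_coli_1d	8	1.849230769	2434.219716
C12_E_coli_1d	9	1.858461538	8.390588026
C12_E_coli_1d	10	1.867692308	0.01043406638
C12_E_coli_1d	11	1.876923077	2.181068321e-06
C12_E_coli_1d	12	1.886153846	0
C12_E_coli_1d	13	1.895384615	0
C13_E_coli_2d	1	1.784615385	179190.9788
C13_E_coli_2d	2	1.793846154	3990394.972
C13_E_coli_2d	3	1.803076923	15596122.39
C13_E_coli_2d	4	1.812307692	36305907.04
C13_E_coli_2d	5	1.821538462	18858757.97
C13_E_coli_2d	6	1.830769231	4248609.387
C13_E_coli_2d	7	1.84	477427.0063
C13_E_coli_2d	8	1.849230769	1923728.117
C13_E_coli_2d	9	1.858461538	2472607.006
C13_E_coli_2d	10	1.867692308	739118.1843
C13_E_coli_2d	11	1.876923077	88821.83014
C13_E_coli_2d	12	1.886153846	2711.758849
C13_E_coli_2d	13	1.895384615	32.33790108
C12_E_coli_2d	1	1.784615385	212861.3427
C12_E_coli_2d	2	1.793846154	4906160.017
C12_E_coli_2d	3	1.803076923	26436357
C12_E_coli_2d	4	1.812307692	50409231.71
C12_E_coli_2d	5	1.821538462	22729817.18
C12_E_coli_2d	6	1.830769231	3605836.603
C12_E_coli_2d	7	1.84	181790.1331
C12_E_coli_2d	8	1.849230769	2706.157727
C12_E_coli_2d	9	1.858461538	7.098269817
C12_E_coli_2d	10	1.867692308	0.007600699369
C12_E_coli_2d	11	1.876923077	2.480342226e-06
C12_E_coli_2d	12	1.886153846	0
C12_E_coli_2d	13	1.895384615	0
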