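# sipscreen output
# bundle: sipscreen-fixture-v1
# seed: 20230211
taxon	genus	baseline_relab	alpha	role	prey
t0000	g_t0000	0.02920441349	0.9479740995	predator	
t0001	g_t0001	0.02100404024	0.6521702283	predator	
t0002	g_t0002	0.001458779318	0.180509763	cross_feeder	
t0003	g_t0003	0.01682044556	0	inactive	
t0004	g_t0004	0.02301486389	0	inactive	
t0005	g_t0005	0.2683493341	0	inactive	
t0006	g_t0006	0.0008994132587	0	inactive	
t0007	g_t0007	0.005568126993	0	inactive	
t0008	g_t0008	0.001342637398	0	inactive	
t0009	g_t0009	0.1956458688	0	inactive	
t0010	g_t0010	0.001101708598	0	inactive	
t0011	g_t0011	0.0002205385505	0	inactive	
t0012	g_t0012	0.0185715677	0	inactive	
t0013	g_t0013	0.02845770433	0	inactive	
t0014	g_t0014	0.0754856006	0	inactive	
t0015	g_t0015	0.06525431209	0	inactive	
t0016	g_t0016	0.01894837736	0	inactive	
t0017	g_t0017	0.03052624324	0	inactive	
t0018	g_t0018	0.04682044307	0	inactive	
t0019	g_t0019	0.0036476533	0	inactive	
t0020	g_t0020	0.01049654403	0	inactive	
t0021	g_t0021	0.00101153963	0	inactive	
t0022	g_t0022	0.05709578263	0	inactive	
t0023	g_t0023	0.002512027003	0	inactive	
t0024	g_t0024	9.591068074e-05	0	inactive	
t0025	g_t0025	0.002335306164	0	inactive	
t0026	g_t0026	0.03717423371	0	inactive	
t0027	g_t0027	0.0005816216724	0	inactive	
t0028	g_t0028	0.008187097956	0	inactive	
t0029	g_t0029	0.01816786459	0	inactive	
prey_E_coli	g_prey_E_coli	0.01	1	prey_spike	E_coli
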