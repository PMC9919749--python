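# sipscreen output
# config_hash: ab8a87cb7745
# seed: 20230211
# version: 0.1.0
taxon	level	prey	timepoint	r13H	r13L	r12H	r12L	ef	passed_filter	labeled	status
prey_E_coli	genus	E_coli	1d	0.2000797528	9.969095803e-05	0.01126507826	0.008872495265	2005.730337	True	True	ok
t0000	genus	E_coli	1d	0.5390290101	0.00149536437	0.02781377729	0.02901006879	359.5079038	True	True	ok
t0001	genus	E_coli	1d	0.2527165786	0.006479912272	0.02123417406	0.02083541023	37.98086124	True	True	ok
prey_E_coli	genus	E_coli	2d	0.1881168378	9.969095803e-05	0.01026816868	0.008274349516	1885.759036	True	True	ok
t0000	genus	E_coli	2d	0.5408234473	0.002093510119	0.02402552089	0.02601934005	257.4099617	True	True	ok
t0001	genus	E_coli	2d	0.2638819659	0.009869404845	0.02322799322	0.01904097298	25.51747845	True	True	ok
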