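subject	quadrature_z_roi	phi_hat_deg	consistency_f4	consistency_f6	distance_t_mean	rsa_rho	rsa_fisher_z	vtest_p	tsnr_roi	phi_true_deg
0	-0.039153	58.607373	-0.758688	1.037570	0.737217	-0.004517	-0.004517	0.020770	8.300714	2.456513
1	0.368997	53.380716	-1.315611	1.109202	0.335651	0.015986	0.015987	0.049055	8.441541	51.505471
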