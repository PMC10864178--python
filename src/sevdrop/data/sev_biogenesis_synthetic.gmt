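SEV_BIOGENESIS_SYNTHETIC	synthetic placeholder biogenesis set	SEVS0001	SEVS0002	SEVS0003	SEVS0004	SEVS0005	SEVS0006	SEVS0007	SEVS0008	SEVS0009	SEVS0010	SEVS0011	SEVS0012	SEVS0013	SEVS0014	SEVS0015	SEVS0016	SEVS0017	SEVS0018	SEVS0019	SEVS0020	SEVS0021	SEVS0022	SEVS0023	SEVS0024	SEVS0025	SEVS0026	SEVS0027	SEVS0028	SEVS0029	SEVS0030	SEVS0031	SEVS0032	SEVS0033	SEVS0034	SEVS0035	SEVS0036	SEVS0037	SEVS0038	SEVS0039	SEVS0040	SEVS0041	SEVS0042	SEVS0043	SEVS0044	SEVS0045	SEVS0046	SEVS0047	SEVS0048	SEVS0049	SEVS0050
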