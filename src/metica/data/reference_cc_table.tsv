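# Reference Pearson correlations between 15 group temporal components and
# 8 movie codings/features from the published naturalistic-viewing study this
# pipeline re-implements (transcribed reference values; regression fixture for
# the |cc| > 0.35 flagging rule).
gtc	exp_var	language	face	music	negative_face	spl	msq_temporal_contrast	std_local_contrast	sound_envelope
1	0.08	0.677	0.215	0.196	0.311	-0.268	-0.226	0.259	-0.211
2	0.11	0.245	-0.050	0.070	-0.011	0.129	0.192	-0.048	0.134
3	0.11	0.186	0.026	-0.121	-0.121	0.210	0.099	0.488	0.365
4	0.05	-0.060	-0.167	-0.291	0.043	0.403	-0.038	-0.039	0.234
5	0.06	0.174	0.128	0.037	0.048	-0.058	0.162	0.045	0.011
6	0.05	0.020	-0.080	0.058	0.139	-0.091	0.069	0.013	-0.062
7	0.04	-0.135	0.052	-0.061	-0.019	-0.073	0.191	-0.124	-0.076
8	0.04	-0.223	-0.480	-0.100	-0.274	0.053	-0.082	-0.129	0.138
9	0.04	-0.064	-0.088	-0.101	0.070	0.124	0.095	-0.132	0.067
10	0.09	-0.078	-0.227	-0.359	-0.261	0.143	0.046	0.146	-0.053
11	0.06	0.118	0.166	0.047	0.107	-0.049	-0.120	0.008	-0.069
12	0.06	-0.118	0.197	-0.041	-0.127	0.129	0.505	-0.047	0.361
13	0.06	0.014	-0.063	-0.250	-0.264	0.256	0.136	-0.120	0.275
14	0.12	0.188	0.202	-0.019	0.390	-0.130	-0.198	0.010	-0.243
15	0.06	-0.100	-0.120	-0.016	0.015	0.103	0.358	0.002	0.233
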