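gene	LumA	LumB	Her2	Basal	Normal
ACTR3B	-0.724	0.44	0.788	1.135	-1.388
ANLN	-1.126	0.732	0.521	0.896	-1.113
BAG1	1.22	0.894	-0.583	-0.718	0.417
BCL2	0.785	0.792	-0.84	-0.78	0.288
BIRC5	-0.846	0.53	0.906	0.861	-1.007
BLVRA	0.912	0.833	-0.509	-0.897	0.408
CCNB1	-0.265	0.598	0.472	0.697	-0.746
CCNE1	-0.518	0.672	0.39	0.694	-0.737
CDC20	-0.614	0.836	0.434	0.958	-0.871
CDC6	-0.745	0.918	0.656	1.07	-0.883
CDH3	-0.528	-0.342	-0.564	1.02	0.082
CENPF	-0.96	0.631	0.974	0.684	-0.658
CEP55	-1.221	0.616	0.641	1.047	-0.722
CXXC5	1.198	0.613	-0.716	-0.786	0.252
EGFR	-0.919	-0.783	-0.43	1.224	0.236
ERBB2	-0.027	-0.007	1.24	-0.144	-0.377
ESR1	1.114	0.535	-0.691	-1.095	0.001
EXO1	-0.678	0.583	0.603	1.02	-0.788
FGFR4	-0.034	0.075	1.094	-0.32	-0.722
FOXA1	0.638	0.369	-0.849	-0.9	0.074
FOXC1	-0.695	-0.175	-0.289	1.284	-0.033
GPR160	0.949	0.462	-0.685	-0.79	-0.132
GRB7	-0.091	0.159	1.051	-0.662	-0.282
KIF2C	-0.932	0.758	0.605	1.3	-0.96
KRT14	-0.856	-0.455	-0.145	1.44	0.409
KRT17	-0.511	-0.134	-0.497	0.94	-0.032
KRT5	-0.697	-0.844	-0.041	1.044	-0.168
MAPT	0.746	0.778	-0.39	-0.501	1.028
MDM2	1.104	0.453	-1.133	-0.933	0.097
MELK	-0.904	0.547	0.565	1.166	-0.861
MIA	-0.64	-0.759	-0.619	0.978	0.187
MKI67	-0.358	0.733	0.846	0.775	-1.196
MLPH	0.759	0.519	-0.068	-1.205	0.51
MMP11	-0.426	0.333	1.296	-0.339	-0.31
MYBL2	-0.964	0.812	0.486	0.594	-1.219
MYC	-0.557	-0.105	-0.16	1.07	0.271
NAT1	1.327	0.755	-0.703	-0.723	0.407
NDC80	-0.416	0.746	0.294	0.558	-0.487
NUF2	-0.369	0.655	0.504	1.265	-1.177
ORC6	-1.024	0.861	0.501	0.899	-0.941
PGR	1.084	1.052	-0.577	-0.839	-0.213
PHGDH	-0.612	-0.711	-0.505	0.88	0.116
PTTG1	-0.571	0.368	0.608	0.779	-0.982
RRM2	-0.549	0.835	0.934	0.861	-1.074
SFRP1	-0.656	-0.439	-0.156	0.829	0.223
SLC39A6	1.057	1.329	-0.131	-1.213	0.228
TMEM45B	0.634	0.552	-0.521	-0.699	0.118
TYMS	-0.964	0.163	0.559	0.634	-1.032
UBE2C	-1.019	0.676	0.161	0.533	-0.368
UBE2T	-1.122	0.426	1.059	1.626	-1.193
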