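gene	snp	fst_yri_chb	fst_yri_ceu	fst_ceu_chb	h_ceu	h_chb	h_yri	d_ceu	d_chb	d_yri	daf_ceu	daf_chb	daf_yri
AARS2	rs325011	0.515	0.431	0.033	-22.591	2.921	4.865	-0.570	1.367	-0.256	0.965		0.494
ANAPC16	rs6480601	0.598	0.161	0.286	-22.942	-10.310	1.234	-1.396	-0.441	0.192	0.300	0.711	0.068
BCKDHB	rs1811844	0.576	0.671	0.012	-38.938	-19.428	7.135	1.177	2.415	1.659	0.824	0.747	0.114
BVES	rs221655	0.547	0.604	0.002	-35.485	-31.006	12.059	-1.424	-1.052	-0.038	0.112	0.155	0.767
CD209	rs12460694	0.356	0.520	0.352	-36.930	-11.461	-19.954	0.197	1.798	0.143		0.371	
CEP104	rs7528951	0.868	0.395	0.380	-4.847	-5.501	-23.971	1.174	1.139	-0.288	0.453	0.041	0.915
CMBL	rs10076725	0.229	0.194	0.594	-19.559	-56.996	-16.407	0.535	-1.263	0.747	0.700	0.072	0.369
DDX51	rs11246938	0.594	0.518	0.006	-20.098	-10.953	-0.296	-1.375	-0.993	-0.631	0.124	0.077	0.710
DDX51	rs12424892	0.584	0.533	0.001	-20.098	-10.953	-0.296	-1.375	-0.993	-0.631	0.900	0.928	0.307
DHRS4-AS1	rs112851730	0.597	0.469	0.055	-75.557	-79.678	-22.540	-1.110	-2.340	1.297	0.929	0.995	0.403
DHRS4-AS1	rs113551151	0.603	0.476	0.055	-75.557	-79.678	-22.540	-1.110	-2.340	1.297	0.071	0.005	0.602
DPPA4	rs3792321	0.657	0.431	0.100	-7.961	-2.900	-32.118	1.955	1.349	0.436	0.465	0.696	0.017
DUSP19	rs10200193	0.705	0.206	0.342	1.123	-33.184	8.978	0.422	-1.361	-0.419	0.535	0.933	0.205
EEF1E1-BLOC1S5	rs2748375	0.658	0.260	0.267	-10.041	-52.521	-3.838	2.184	0.019	0.793	0.300	0.696	0.017
EGF	rs7653900	0.031	0.610	0.460	-27.671	4.260	-2.875	-1.107	1.438	-0.173	0.912	0.381	0.256
FBXL19-AS1	rs12930657	0.781	0.426	0.237	-2.038	-24.287	0.098	0.982	-2.090	-0.608	0.700	0.969	0.182
FBXL20	rs4325601	0.523	0.455	0.003	-15.787	-20.654	9.685	1.005	-0.167	-0.544	0.718	0.773	0.176
FOXL2NB	rs7649365	0.479	0.678	0.103	-46.982	-33.494	4.819	-2.276	-1.161	0.100	0.982	0.845	0.290
FTLP10	rs11131742	0.562	0.162	0.261	-9.842	-43.181	-14.138	1.605	-2.103	0.229	0.265	0.005	0.563
GINS1	rs6037121	0.538	0.013	0.436	6.849	-44.913	9.490	1.482	-0.883	-0.293	0.459	0.938	0.364
GPSM2	rs12743716	0.597	0.240	0.206	-3.468	-34.839	9.503	0.276	-1.361	0.096	0.729	0.969	0.358
HES2	rs4908889	0.683	0.524	0.054	-38.218	-24.711	1.574	-1.022	-0.268	0.368	0.835	0.943	0.239
HSH2D	rs432781	0.594	0.230	0.205	-14.433	-28.230	-22.427	0.662	-1.066	-0.251	0.700	0.954	0.335
HTATSF1P2	rs4269412	0.357	0.661	0.149	-63.325	-17.117	-34.270	0.292	2.050	0.862	0.659	0.371	
ITPRIPL2	rs57236534	0.406	0.571	0.063	-30.751	-9.522	0.460	-1.788	-0.660	0.033	0.965	0.856	0.364
IVD	rs2075625	0.599	0.193	0.232	8.014	-22.145	-8.386	1.617	-0.148	-0.562	0.541	0.191	0.847
IVD	rs4923865	0.597	0.315	0.119	8.014	-20.713	-5.243	1.617	-0.113	-0.434	0.600	0.830	0.176
IVD	rs11630878	0.605	0.194	0.239	9.854	-20.713	-5.243	1.613	-0.113	-0.434	0.459	0.814	0.153
IVD	rs11630850	0.605	0.194	0.239	9.854	-20.713	-5.243	1.613	-0.113	-0.434	0.459	0.814	0.153
LILRA6/LILRB2/LILRB3	rs2361804	0.612	0.313	0.142	-12.116	-51.447	-11.251	2.144	0.532	1.716	0.300	0.082	0.733
LOC105447645	rs570794	0.566	0.003	0.531	-7.253	-41.168	-9.092	1.619	-1.065	1.351	0.453	0.985	0.415
LOC105447645	rs571689	0.566	0.003	0.531	-7.253	-41.168	-9.092	1.619	-1.065	1.351	0.453	0.985	0.415
LOC105447645	rs507711	0.502	0.004	0.531	-5.990	-41.168	-9.092	2.050	-1.065	1.351	0.547	0.015	0.523
MRPS10	rs3199639	0.539	0.388	0.033	-5.530	-33.620	-14.099	1.878	0.015	-0.469	0.359	0.232	0.841
MRPS10	rs9381159	0.572	0.388	0.051	-5.530	-33.620	-14.099	1.878	0.015	-0.469	0.359	0.206	0.841
MS4A10	rs12577187	0.519	0.004	0.539	5.805	-21.114	1.036	0.666	-0.562	-0.736	0.071	0.665	0.085
NMT2	rs2400118	0.723	0.557	0.055	-34.558	-36.623	5.111	-1.017	-0.974	-0.098	0.706	0.851	0.097
NOL9	rs10158065	0.337	0.531	0.060	-62.005	-42.239	-2.763	-0.661	0.708	0.670	0.894	0.753	0.301
NOL9	rs11122049	0.337	0.529	0.058	-62.005	-42.239	-2.763	-0.661	0.708	0.670	0.888	0.747	0.296
PSMB2	rs12082263	0.002	0.721	0.666	-41.524	-34.361	-16.777	-2.653	-1.647	-1.155	0.894	0.186	0.142
PSMB2	rs11264180	0.478	0.077	0.647	-41.524	-34.361	-16.777	-2.653	-1.647	-1.155	0.029	0.706	0.148
RAB3B	rs4537499	0.582	0.304	0.115	-22.665	-27.025	-3.451	-1.002	-1.200	-0.501	0.618	0.840	0.199
RNF168	rs9872866	0.677	0.157	0.367	-2.861	-20.418	12.103	0.419	-0.451	-0.852	0.359	0.825	0.108
RNF168	rs59487085	0.609	0.085	0.372	-2.861	-20.418	12.103	0.419	-0.451	-0.852	0.459	0.902	0.250
RNF207	rs11121500	0.492	0.549	0.005	-38.594	-31.318	5.294	-1.766	-1.173	0.431	0.924	0.881	0.324
RPP14	rs3210776	0.791	0.272	0.422	-12.302	-51.579	-9.828	1.159	-0.921	0.137	0.300	0.814	0.011
RPP14	rs1135089	0.806	0.299	0.422	-11.166	-45.431	-12.550	1.339	-0.485	0.216	0.300	0.814	
RSU1	rs45461296	0.351	0.545	0.060	-24.623	-15.202	-6.458	-1.627	-1.036	-0.671	0.894	0.753	0.290
RSU1	rs45514294	0.372	0.538	0.041	-24.623	-15.202	-6.458	-1.627	-1.036	-0.671	0.871	0.747	0.267
S1PR3	rs1129925	0.641	0.219	0.253	-17.269	-27.133	-6.914	-0.631	-0.653	-1.032	0.453	0.820	0.131
SEPN1	rs3203750	0.524	0.205	0.165	-11.257	-48.385	3.951	0.973	-1.548	0.086	0.747	0.959	0.409
SLC28A2	rs2458225	0.681	0.017	0.578	-2.327	-30.633	5.342	2.017	-1.036	0.435	0.329	0.938	0.233
SLC35E2	rs61777506	0.304	0.603	0.140	-33.670	-7.388	7.536	0.473	1.735	0.105	0.071	0.289	0.716
SMIM12	rs11263953	0.677	0.035	0.535	-2.822	-27.384	-0.592	1.154	-0.946	0.126	0.377	0.943	0.244
SMIM12	rs6697614	0.653	0.433	0.106	-2.822	-27.384	-0.592	1.154	-0.946	0.126	0.835	0.974	0.313
STAT2	rs4996382	0.719	0.669	0.020	-23.481	-7.815	-11.120	-2.178	-1.995	-0.093	0.024		0.710
TMEM40	rs4684873	0.621	0.212	0.269	0.313	-27.455	-5.997	0.874	-0.510	-1.120	0.288	0.686	0.034
TMPRSS11B	rs13125514	0.625	0.228	0.261	-13.452	-43.633	-10.160	1.170	-2.222	-0.604	0.735	0.995	0.375
TNFRSF25	rs3007418	0.651	0.548	0.050	-14.520	-20.331	0.138	-1.266	-1.810	-0.696	0.053		0.642
TNFRSF9	rs12564367	0.228	0.196	0.556	-22.980	-1.339	-13.523	-0.593	1.016	-0.610	0.982	0.397	0.756
TP73-AS1	rs1181864	0.036	0.711	0.582	-26.005	-9.417	-3.538	-0.347	0.676	-0.250	0.188	0.830	0.926
TRIP13	rs6555582	0.288	0.712	0.262	-33.963	-0.155	-0.175	-2.277	-0.839	0.056			
TSPAN16	rs411834	0.396	0.501	0.022	-26.646	-7.999	3.643	-0.730	0.365	0.324	0.059	0.129	0.608
TSPAN16	rs445026	0.403	0.507	0.022	-26.646	-7.999	3.643	-0.730	0.365	0.324	0.941	0.871	0.386
TSPAN16	rs445169	0.396	0.501	0.022	-26.646	-7.999	3.643	-0.730	0.365	0.324	0.941	0.871	0.392
VHL	rs1136249	0.571	0.442	0.024	-11.630	-28.103	5.172	0.595	-0.693	-0.382	0.694	0.799	0.165
VHL	rs1681668	0.513	0.387	0.021	-11.630	-28.103	5.172	0.595	-0.693	-0.382	0.694	0.794	0.205
VSTM4	rs4240499	0.755	0.527	0.105	-16.215	-22.284	12.465	0.030	0.400	0.094	0.624	0.835	0.057
ZDHHC8P1	rs12485210	0.506	0.357	0.035	-80.877	-69.594	-42.037	-0.058	0.275	0.247			
ZDHHC8P1	rs6003681	0.506	0.357	0.035	-80.877	-69.594	-42.037	-0.058	0.275	0.247	0.171	0.077	0.631
ZNF106	rs1139100	0.840	0.863	0.005	-9.112	-24.650	4.460	-0.488	-0.853	-0.317	0.877	0.861	0.011
ZNF175	rs4801879	0.663	0.096	0.507	2.295	-54.041	-5.147	1.530	-0.264	0.377	0.100	0.675	
ZNF197	rs9865162	0.555	0.079	0.323	-4.990	-20.126	-15.882	-0.637	-1.949	-1.178	0.424	0.845	0.227
ZNF500	rs921864	0.660	0.457	0.076	-11.268	-20.000	1.246	1.070	1.503	0.094	0.541	0.737	0.045
ZNF528	rs8106133	0.181	0.725	0.391	-50.846	-18.850	-4.816	-1.064	0.594	0.263	0.818	0.325	0.068
ZNF670	rs12144260	0.510	0.031	0.377	4.999	-40.482	12.912	0.966	-1.833	0.227	0.377	0.005	0.511
ZNF696	rs7387702	0.688	0.400	0.158	2.706	-25.135	-16.796	2.837	2.149	-0.008	0.424	0.717	0.011
ZNF860	rs13094125	0.419	0.543	0.018	-38.882	-1.324	-37.144	-0.121	2.272	-0.886	0.788	0.691	0.176
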