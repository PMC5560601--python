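gene	logFC	t	p	d0	s0_2
g000	 1.1169508661400	 3.1197676792753	1.32813011799e-02	2.46177520271	0.332964244114
g001	 1.5180399242990	 5.3618614585750	5.60377239958e-04	2.46177520271	0.332964244114
g002	-0.5863322689641	-0.6765528853048	5.16753756418e-01	2.46177520271	0.332964244114
g003	 1.3835496689257	 3.8823211413567	4.18298637261e-03	2.46177520271	0.332964244114
g004	 0.9717266792593	 4.2314621164661	2.52941546699e-03	2.46177520271	0.332964244114
g005	-0.6277249723371	-2.7626778819052	2.33055283028e-02	2.46177520271	0.332964244114
g006	-0.6087909571902	-2.2521553650680	5.26310089957e-02	2.46177520271	0.332964244114
g007	-0.3798948380764	-0.7458747818932	4.75951124471e-01	2.46177520271	0.332964244114
g008	-0.7171087440903	-1.1080750586829	2.98329494198e-01	2.46177520271	0.332964244114
g009	-0.0688084030010	-0.1505722622913	8.83840983298e-01	2.46177520271	0.332964244114
g010	 0.5346386851537	 0.8988317388189	3.93600102078e-01	2.46177520271	0.332964244114
g011	-1.7193596593395	-1.5553620223442	1.56416586429e-01	2.46177520271	0.332964244114
g012	-0.5380042412724	-0.7856755350168	4.53494070723e-01	2.46177520271	0.332964244114
g013	 1.2943353497517	 3.5497529897293	6.86177598469e-03	2.46177520271	0.332964244114
g014	-2.5833804033637	-4.5096625315412	1.71568665090e-03	2.46177520271	0.332964244114
g015	-0.3736193111973	-1.0445034833673	3.25171615504e-01	2.46177520271	0.332964244114
g016	-0.4700574541096	-0.9372023374533	3.74630011976e-01	2.46177520271	0.332964244114
g017	 1.8265144120935	 2.5321873913331	3.36458390158e-02	2.46177520271	0.332964244114
g018	 0.4477502145758	 1.7256197907950	1.20635303448e-01	2.46177520271	0.332964244114
g019	 0.1972704693573	 0.7943509383790	4.48694376170e-01	2.46177520271	0.332964244114
g020	-1.5906510670284	-1.5137287508202	1.66513017147e-01	2.46177520271	0.332964244114
g021	-0.1776462626741	-0.1586562116265	8.77661326238e-01	2.46177520271	0.332964244114
g022	 1.1507600031495	 1.1929398387017	2.65267707247e-01	2.46177520271	0.332964244114
g023	-0.9742142430805	-3.7839780606997	4.83473845776e-03	2.46177520271	0.332964244114
g024	-1.2130987251503	-4.2438156053495	2.48559304842e-03	2.46177520271	0.332964244114
g025	 0.7475194677865	 1.8568701832173	9.83895493610e-02	2.46177520271	0.332964244114
g026	-2.4815267489240	-8.2499659036538	2.50996399451e-05	2.46177520271	0.332964244114
g027	-0.7821306703933	-1.3392026802032	2.15362278011e-01	2.46177520271	0.332964244114
g028	-0.1213471740876	-0.3583678695165	7.28844915637e-01	2.46177520271	0.332964244114
g029	-1.5253240471093	-2.5710451114652	3.16218304726e-02	2.46177520271	0.332964244114
g030	 0.5118481280482	 1.5795114170992	1.50814914125e-01	2.46177520271	0.332964244114
g031	 0.1529694110361	 0.2763285328307	7.88925640747e-01	2.46177520271	0.332964244114
g032	 0.5213698982412	 1.3435713359345	2.14002841543e-01	2.46177520271	0.332964244114
g033	-1.5095264948402	-3.4176695483212	8.38574518799e-03	2.46177520271	0.332964244114
g034	-0.4898089135022	-1.0330295200142	3.30209644287e-01	2.46177520271	0.332964244114
g035	-0.1036385502986	-0.2640708708230	7.98043488602e-01	2.46177520271	0.332964244114
g036	-2.9936888116262	-3.7765404908602	4.88824029815e-03	2.46177520271	0.332964244114
g037	 0.2631917862507	 0.7722039981906	4.61015027041e-01	2.46177520271	0.332964244114
g038	 2.2294211307857	 8.6267737514353	1.78379666190e-05	2.46177520271	0.332964244114
g039	 2.3265766432037	 2.4847637932195	3.62939627294e-02	2.46177520271	0.332964244114
g040	-0.6871486111241	-2.7014853592461	2.56861543514e-02	2.46177520271	0.332964244114
g041	 0.4022434783752	 0.9060032084451	3.90002954111e-01	2.46177520271	0.332964244114
g042	-1.5594467245784	-3.9152397476198	3.98627030367e-03	2.46177520271	0.332964244114
g043	-0.8819278579934	-2.0280739458623	7.51579954433e-02	2.46177520271	0.332964244114
g044	-0.0723898153974	-0.1283688069813	9.00855967017e-01	2.46177520271	0.332964244114
g045	-0.2964553342461	-1.1217203243865	2.92802089794e-01	2.46177520271	0.332964244114
g046	 1.2540494355897	 1.5296623479909	1.62582231933e-01	2.46177520271	0.332964244114
g047	-1.9784629913777	-3.5425727677709	6.93661059810e-03	2.46177520271	0.332964244114
g048	 2.3037242819640	 4.5340894579358	1.65909461332e-03	2.46177520271	0.332964244114
g049	-0.0544680261388	-0.0833962221733	9.35475851930e-01	2.46177520271	0.332964244114
g050	 0.0301087767518	 0.0520142162055	9.59724445309e-01	2.46177520271	0.332964244114
g051	 0.3618225314404	 0.8474314547057	4.20076736069e-01	2.46177520271	0.332964244114
g052	-1.5057825963481	-1.7166287178316	1.22318913257e-01	2.46177520271	0.332964244114
g053	 0.1640894880691	 0.3468338542025	7.37184577890e-01	2.46177520271	0.332964244114
g054	-0.1974088162498	-0.3997712555904	6.99227346790e-01	2.46177520271	0.332964244114
g055	 0.6344956670905	 0.5916294529487	5.69564313277e-01	2.46177520271	0.332964244114
g056	-0.9284929945721	-1.2817062836250	2.33948621500e-01	2.46177520271	0.332964244114
g057	-3.7548400565393	-4.3417321427507	2.16576266422e-03	2.46177520271	0.332964244114
g058	 0.4737318931295	 0.7755471438019	4.59140920053e-01	2.46177520271	0.332964244114
g059	-0.3966388085362	-0.5113559874837	6.22175940363e-01	2.46177520271	0.332964244114
g060	 0.6522379252186	 1.3343471015432	2.16881869714e-01	2.46177520271	0.332964244114
g061	-2.0595282084702	-3.3815485443831	8.86183324893e-03	2.46177520271	0.332964244114
g062	 2.5212937963627	 8.3660989537476	2.25621537611e-05	2.46177520271	0.332964244114
g063	-0.8234332284547	-1.1757253896759	2.71722914695e-01	2.46177520271	0.332964244114
g064	-1.5421534677919	-3.6821307837754	5.62478076933e-03	2.46177520271	0.332964244114
g065	 0.0674803655903	 0.1483761855115	8.85521210357e-01	2.46177520271	0.332964244114
g066	-0.0850665705213	-0.1603302804911	8.76382697973e-01	2.46177520271	0.332964244114
g067	-0.2476144133308	-0.3480762063825	7.36284506294e-01	2.46177520271	0.332964244114
g068	 0.3646027881197	 0.8598766851949	4.13554330550e-01	2.46177520271	0.332964244114
g069	-1.2840120148513	-3.3533768476533	9.25282208471e-03	2.46177520271	0.332964244114
g070	-0.2736297248427	-0.7222839770147	4.89597959012e-01	2.46177520271	0.332964244114
g071	-0.2924696972452	-0.4970076031734	6.31839244527e-01	2.46177520271	0.332964244114
g072	-1.4000096980526	-1.8940081193643	9.28327562693e-02	2.46177520271	0.332964244114
g073	 0.2663865924328	 0.5575452779296	5.91595553444e-01	2.46177520271	0.332964244114
g074	-2.9607414108199	-7.1899456436304	7.04298739709e-05	2.46177520271	0.332964244114
g075	-0.3998364895833	-0.7755845520182	4.59119978333e-01	2.46177520271	0.332964244114
g076	 0.4827422068758	 0.5227354397927	6.14566536574e-01	2.46177520271	0.332964244114
g077	 1.0051376287065	 3.2674025652788	1.05619098736e-02	2.46177520271	0.332964244114
g078	 0.4485913578082	 1.4963177773060	1.70904713185e-01	2.46177520271	0.332964244114
g079	 0.1362154559033	 0.2134709282948	8.36013819389e-01	2.46177520271	0.332964244114
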