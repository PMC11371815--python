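protein_id	S01	S02	S03	S04	S05	S06	S07	S08	S09	S10	S11	S12
G01	9.25516364260719	6.736755323870851	10.892805100580567	10.118745457230496	6.587989023457972	6.963881361740075	14.077060613195078	11.166449119382701	13.282298103132371	10.27184083508676	14.31917073738813	12.040852553600796
G02	10.39208241366515	12.964648121550695	12.639291054381639	11.53166465519882	10.910374587224787	9.21903732723587	13.287713597375074	15.391831285909554	12.965981255454365	13.787024089298699	13.218531094533391	14.990766682998876
G03	9.88096915299901	9.0878450991063	10.255299723297803	11.747135108195293	10.679537050233387	11.204855432775904	16.093260054536977	12.995301897693952	12.407377397423947	14.369583147182578	10.967355643687757	15.315808252947496
G04	10.070457896132428	8.425054059223521	8.25468847069419	7.854108368317555	11.56341200804128	12.457386404797896	9.904194337437682	13.810038467492781	12.725773548796193	12.524692193389441	12.867314317348658	12.15854740744883
G05	12.258478830051326	9.154658166849927	12.08612573722011	10.567558412532303	8.23310968420866	9.681523426479819	12.713195223934097	11.328995111836845	12.30438851526882	13.803386357074018	11.035982915928269	13.893875105609151
G06	6.59451327604207	7.118216155328156	10.101553194136637	8.790709573683914	11.628369406055796	9.58704324178189	13.023414617264383	8.166309575431837	14.236893590327334	8.87204132814997	10.698880344191423	9.465696752214456
G07	9.090468734624332	9.68736986706028	9.466871173532178	10.516381857171249	8.462926956123408	9.19991024603262	14.168231225541572	12.843559577004914	14.133614520966859	9.775708836751946	12.679634743977667	11.93696207334254
G08	8.721953737644851	15.164694076630894	6.725072133252325	11.702632881450004	11.457397704845526	11.119522569019647	15.837131254245572	15.731664385130394	13.419908267720068	14.589433740417167	11.482959527504454	14.581077120409049
G09	8.322550508468998	9.247618923507208	10.955586804326312	7.940012280817739	9.238524516827313	12.18292031619766	12.970368429304056	15.857494996560206	10.20593793949528	12.962144950197533	13.525405016082996	11.947349622708469
G10	10.762772294560586	6.971898582496173	11.162723312073002	9.80394705841899	9.913165780836312	7.789939548966265	13.617729495240694	11.98158322229174	14.757891716176035	12.349026059139208	14.189980211094419	13.052414272277675
G11	8.205440094635268	10.795114283169584	11.071932565097098	11.596087238233086	10.543535053936761	10.093168600502967	14.745029388085912	11.931015640996671	12.337355965929182	12.231741880638634	11.614870270943015	10.091241425659025
G12	11.012212813818703	7.589380028390107	8.29655781146341	7.683914704126717	10.621566848146216	10.528146736417522	16.245952981485082	16.389956003795948	12.850396009080097	9.75816168926572	10.017288963307003	12.738622826088893
G13	8.526163346405923	9.416405083436262	8.91007688680606	9.415537704085928	12.13498335668578	8.650387202634414	11.924302014203839	10.191447461302978	8.98005528408071	11.534938439976752	13.40359030806758	15.170487046278952
G14	10.457417220985125	13.01643415306161	11.009794877771764	8.230477277056377	10.345371613271015	9.133675261626175	15.083433158396764	11.080016592826857	12.296520104746524	10.56860759351224	13.923107633033391	14.741384221332531
G15	11.159442613549137	8.732725951408865	9.336140175256736	9.73981881676118	9.702188289881367	7.9692666441872415	9.599447163146724	13.925012464729479	14.878383829277956	12.721248892968688	11.955185039453253	12.81245013191418
G16	12.234509257710348	10.998030754133291	9.59522539245318	12.683270510453578	11.49347163063821	12.873729728131282	12.323944358576856	12.641257134377666	10.734325271006172	16.98485281180202	15.83234434409664	13.43709152670909
G17	9.920819265251216	15.309142903990972	11.290759480651515	9.101143242173652	11.192616295107376	11.282043027011644	11.79065784262425	13.572764043200216	13.469611479921538	15.901922317759158	11.95168489440639	12.0518249441334
G18	5.545105611096486	9.851593841537817	8.429891641998925	8.644978125718715	9.972060242475056	10.903214529864979	13.733551655446869	11.910147946867955	12.775023758965355	12.75281871309319	12.631830457179511	15.584540776213462
G19	10.540950210098583	12.152550541296002	8.872139622281846	8.27268818980205	11.702658515300623	9.850428058676906	14.389532243312486	10.756863331170853	13.591482122508998	12.609411299998355	16.642488805178697	14.515219144152404
G20	9.001385706345772	9.910164252730771	8.239872423341025	10.721113011199028	10.71297734291436	12.519499833134136	12.203092226976873	12.714842904468854	10.390552588429465	12.456784978913946	11.187020910883154	11.802434880039366
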