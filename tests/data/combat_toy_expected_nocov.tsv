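	S01	S02	S03	S04	S05	S06	S07	S08	S09	S10	S11	S12
G01	10.94379128532410	 8.59493746050338	12.47117680642016	11.74923154424978	 8.45618700803324	 8.80677199853143	12.21996597730564	 9.51978750404010	11.48266365248765	 8.68985811071633	12.44457188808950	10.33097282885740
G02	11.64438294304395	13.99306976714562	13.69602706987029	12.68479244063858	12.11757046760093	10.57342272223071	12.14686830600675	14.14608508640258	11.84117594846000	12.62128564469501	12.08113490081533	13.76501558229120
G03	11.27609118942178	10.43673346538347	11.67224265397749	13.25104176763640	12.12121009537717	12.67715092178668	14.30123397191913	11.65637770006699	11.15444199816608	12.82965900277600	 9.92503528117740	13.63749089683767
G04	11.41857858240990	 9.92134961305976	 9.76632609311605	 9.40181975104366	12.77708650375984	13.59055510925175	 8.63026066894210	12.37087558276142	11.33247840398042	11.13990340818434	11.46803156281918	10.78924767249647
G05	13.28933198526340	10.43648961032485	13.13091554951048	11.73514121743358	 9.58945853246366	10.92075197650320	11.51514511721151	10.20257959001414	11.12749481405696	12.54891710358105	 9.92473124710707	12.63472291365752
G06	 8.15921323524005	 8.67212076478934	11.59396078307239	10.31013823867777	13.08930396774001	11.09005668204752	11.25142327697158	 6.98607600598732	12.31705994358112	 7.60582603806970	 9.21009498932551	 8.12715438512622
G07	10.34721482004158	10.98379737466229	10.74864013673946	11.86792129703175	 9.67795465821367	10.46393189951758	12.61495158233698	11.50330758566898	12.58590177828371	 8.92881460709347	11.36574439652634	10.74250495699207
G08	10.87068351507221	16.61140862678311	 9.09138654386231	13.52658127138132	13.30806746164585	13.00700794740139	13.87471282040689	13.77168690884148	11.51343478368345	12.65589240032134	 9.62131537888480	12.64772918848842
G09	 9.91748757690707	10.82337394739948	12.49592572770096	 9.54288158994633	10.81446812062483	13.69780948286831	11.39543906491816	13.99615632837694	 8.90524615823509	11.38803137302111	11.89541480185271	10.47390597339017
G10	12.12610711473542	 8.76836782997797	12.48036086874635	11.27683451766538	11.37357422010510	 9.49294176682952	12.09344588064971	10.54280294460741	13.17402438580324	10.89104359324448	12.63579135724600	11.55767345515329
G11	 9.29592047886189	11.86483808052552	12.13943762669792	12.65939112964238	11.61527529264642	11.16851858690048	13.38800372715670	10.88977018434290	11.25051221362200	11.15674982502694	10.60910170193400	 9.25644992756924
G12	13.06380747653748	 9.48295229468765	10.22277845265465	 9.58185136592392	12.65512650433162	12.55739345333456	13.83263173929526	13.95676895852588	10.90550567256895	 8.23985766385847	 8.46323727568949	10.80915205513493
G13	 9.94253171732619	10.85950977137450	10.33797519807474	10.85861634232517	13.65973414986530	10.07048634494314	10.48440453156765	 8.98428751380227	 7.93559590999924	10.14733589368445	11.76501145849712	13.29459849809482
G14	11.91552676757155	14.42287557651325	12.45675158029920	 9.73355010848645	11.80574342947493	10.61851197117019	13.41090229511130	 9.81448246793949	10.90731337335121	 9.35506450960186	12.36853819009183	13.10362685700167
G15	12.63321769625764	10.12475003859150	10.74849202228198	11.16576975070512	11.12687153028590	 9.33557138828274	 8.58520567531286	12.32712486114008	13.15185835872868	11.28578443732926	10.62308515268564	11.36467994392500
G16	13.66211362298966	12.37163298321707	10.90756130273066	14.13047413784689	12.88871181429415	14.32925149820396	11.14106540197774	11.41186052523418	 9.78448246684965	15.11869055713512	14.13513837655009	12.09102659984061
G17	11.39806113195367	16.28864331971427	12.64145437722291	10.65410192924788	12.55237707837222	12.63354309798848	10.51966238353324	12.19539229332340	12.09839704382495	14.38552001076933	10.67107751629550	10.76524007318531
G18	 7.60310090723053	11.46291149551068	10.18867111459617	10.38144839455927	11.57088287845392	12.40545596572828	12.00222048438637	10.28119808366504	11.09751245193060	11.07655418515992	10.96235923333879	13.74927941891794
G19	12.17019445431590	13.77608847835770	10.50729274205242	 9.90996382961210	13.32778941684458	11.48211728346260	12.68360947672167	 9.45559892809542	11.97445753620877	11.10178373872431	14.68559967268845	12.79529558177224
G20	10.09783222948624	10.90761585654256	 9.41927198968289	11.63022647449946	11.62297703953173	13.23271171065505	11.21968093759316	11.71743133159784	 9.45672808004619	11.46643325817956	10.23140692025112	10.82998462438771
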