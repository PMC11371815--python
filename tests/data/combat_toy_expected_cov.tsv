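	S01	S02	S03	S04	S05	S06	S07	S08	S09	S10	S11	S12
G01	11.05773336260485	 8.64392847275723	12.43806583884485	11.49453462508111	 8.80962970799246	 8.83536808534410	12.32908639463037	 9.34041998906616	11.47568684585629	 8.37980811258564	12.58905923950410	10.27933631533997
G02	11.71906013856994	14.02200760496721	13.63471101516449	12.80044945334528	12.16088242361378	10.82903189656861	12.01509798317730	14.21205627322976	11.67138558684044	12.49761213648924	11.94118908208784	13.78359180823577
G03	11.41831704902382	10.62066096297060	11.79375456267702	13.28781483260575	12.21924641362694	12.74393156685588	14.21723827159662	11.58849272485457	10.98204011409664	12.79473627079392	 9.71809436274269	13.62526344800704
G04	11.43541139889567	10.03584986402602	 9.84824081586470	 9.53678418287791	12.74040795574922	13.56052606478056	 8.42960422071538	12.42223158753858	11.31922980888670	11.10588736854307	11.46418403343307	10.73091248278748
G05	13.27188590141872	10.51033438727728	13.11874645542865	11.76572677570936	 9.69525846309620	10.97846555130664	11.48809541800962	10.10499043463057	11.07962017572261	12.57737540774185	 9.81224301794448	12.66779078669396
G06	 8.26194141611493	 8.43676272171708	11.34769570778529	 9.90834669681073	12.69110205289504	10.60902022529170	11.78590318663945	 6.93447640725713	12.99659982912436	 7.63859001983516	 9.46669873215524	 8.23088427846055
G07	10.53170780082884	11.08366878514151	10.89479658316143	11.88335795533362	 9.92636267904947	10.61345100241729	12.63029812842169	11.36891761703341	12.59904675786350	 8.59931428596116	11.28641861046905	10.55045685127984
G08	10.59733997752970	16.60176467071863	 8.82477165759554	13.52860300567444	13.02550662824607	13.01099451823715	14.06727418234512	13.95019573907762	11.63944451285898	12.80295302953466	 9.69399651489471	12.79455974099428
G09	10.03416334620048	10.95175123593026	12.47998324516944	 9.73711915822372	10.88500898782947	13.67834432050301	11.29945627468954	14.07893555199970	 8.67897608337244	11.33435308867023	11.82559082083654	10.37240050432068
G10	12.16740748046853	 8.72233287651191	12.48671386135256	10.98333762394193	11.48911246634378	 9.37542710300761	12.16324615602851	10.51606026500343	13.27478622603340	10.87427897203722	12.72113133155957	11.56000962449750
G11	 9.43218363539575	11.83309723913655	12.11121133643231	12.58168763541641	11.61737031499427	11.17705786423322	13.50881455597213	10.86169591138069	11.26076291680946	11.14248487127241	10.58617593340108	 9.14389340443845
G12	13.04847710305598	 9.61228221391563	10.31936690957288	 9.70728527835741	12.65589561312622	12.56560955932233	13.85416197940870	13.88952485625088	10.88263617931464	 8.08589733160770	 8.40332254995731	10.69416373273802
G13	 9.99092599896400	10.86456340519328	10.36693942432240	10.86371387464464	13.52548425432786	10.11430852502968	10.46578848640047	 8.93282733463638	 7.84559070673717	10.12845134375992	11.78226372042461	13.36386510464831
G14	11.94170639847828	14.23083225985060	12.45286166922938	 9.80203784229788	11.83802243833994	10.63783270958185	13.54942659133053	 9.69769426507183	10.90601114232241	 9.21261761448189	12.44884599890529	13.17053879497683
G15	12.69538869662182	10.28551440886498	10.88540888864076	11.28524857954740	11.24878233799600	 9.52763359805419	 8.40690961823474	12.22493598733667	13.08339528327102	11.15855018969121	10.49380232142077	11.23934321933646
G16	13.54332984173683	12.30165579913702	10.89849558574682	13.99043959982829	12.80073381905892	14.18129935156400	11.10765971711917	11.54473854301659	 9.72571029806768	15.32088187820050	14.15771828756505	12.23660421369394
G17	11.26632634936362	16.12327115245738	12.45962972438501	10.71571623487751	12.37414088828208	12.61541597693536	10.54406992490396	12.33252439109986	12.24371993109164	14.69039407125305	10.70708194827256	10.79283675964070
G18	 7.72294529617923	11.68147068703738	10.29533134974159	10.60552210501682	11.67049503869829	12.61920900222334	11.83580040123939	10.06952147795991	10.89604561650455	10.89568823578009	10.75565680675871	13.67195000930248
G19	12.26262332592807	13.65517688691783	10.72094724158458	10.07089294150713	13.33582955088155	11.52843632055640	12.69194602389030	 9.16952560618813	11.93103575277429	10.93585924923893	14.84005394795934	12.75297414664695
G20	 9.93236123722095	10.90732434466528	 9.27380165055994	11.60863591873639	11.41255220153803	13.16388768983756	11.38668920925966	11.86010866337296	 9.49578387920242	11.59089352649112	10.32668774696908	10.90825240605911
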