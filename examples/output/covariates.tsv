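time	x1	x2	x3	x4	c1	c2
0.0	-0.7305510494955458	-1.8156457590473654	0.07832451139979074	-0.508198762880914	0	0
0.10563086423129525	-1.964653943219463	-1.025123529956199	-0.7487611301213245	-1.1148680383560152	-1	0
0.19285530415379942	-1.461754984015321	-0.064875236305254	0.5599243958170336	-0.0004318244399496322	1	1
0.19466092409894697	-0.5815835250241991	0.3283439749971884	0.38731821526815857	-0.07806347025525628	1	0
0.206952109300433	0.9325595303364235	1.0709513194080245	-0.4988449777607706	-0.6741327849310021	0	1
0.2218891268661839	0.7009980824866846	0.17319457716071135	0.7531938875157906	-1.2209386851255926	0	0
0.41296322364169397	-0.48522582512355544	-1.0523422717985143	-1.963067347326105	0.4169480651254376	0	0
0.5534896855946865	0.9127391370599367	-0.9401670264213687	1.028225415168294	1.2242628196453638	1	0
0.7489167936601724	1.0297700209556195	0.34720968760767273	0.6159408001931045	-1.2759588480436714	0	0
0.7670850327048939	1.0139654866553354	0.5741743144045174	-1.9953842229691399	0.6730122726895272	-1	1
0.7685734702247407	-0.001937493408936936	0.7759400677098843	-0.7213999443007596	0.24901088111512829	0	0
0.8236129033050394	0.6953575488811305	-1.0953430517266385	0.2735608701696652	0.148344819402361	0	0
0.9022475364350362	0.8712243969449155	-0.6952741430447978	0.7411015943645656	0.9726945549527423	1	0
0.9328253891945743	0.08315252075653877	0.6071126430546696	0.9075137553173838	2.3493559507770008	1	1
0.9942644287751989	-1.55708942124992	0.8906349728329648	0.14552720244392978	0.1612323388171924	0	1
1.0055408761537257	-0.8907779188455346	1.3128648993715943	-1.510223940720978	0.9282869331902158	0	1
1.1820593917559878	1.8225242823487764	-1.9119151231388618	-0.5904741812594068	-1.249535852293782	0	0
1.225104653954487	0.579237382494989	1.6031733330839828	1.6398854244063772	-1.7938256196024767	0	1
1.3923165344405541	-0.38336658183577466	0.6879200736614215	1.2139794913794513	0.7591200025682378	0	1
1.5	-0.5845876467021001	0.22916627814636764	-0.3163398189850598	0.03368524764545303	0	0
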