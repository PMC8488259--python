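word	concreteness	familiarity	imageability	age_of_acquisition	frequency
cookie	602	570	604	183	41
jar	589	531	566	239	18
boy	588	612	618	161	142
girl	591	609	614	158	138
woman	577	598	600	208	190
mother	564	620	588	139	160
stool	585	492	545	286	9
chair	601	604	610	177	66
plate	594	575	586	203	45
dish	581	556	561	230	26
dishes	577	560	555	233	22
towel	596	572	580	217	28
water	588	628	602	144	286
window	583	601	589	196	119
curtain	580	520	551	268	21
sink	587	552	560	241	29
kitchen	576	606	592	198	93
floor	570	592	561	204	100
hand	579	622	588	151	254
garden	572	568	583	236	60
house	589	618	611	162	247
street	567	590	570	221	134
door	585	610	589	175	155
morning	460	614	510	202	183
birds	590	580	600	180	70
trees	592	588	606	172	88
people	470	630	489	190	459
flowers	597	586	612	181	55
sun	598	611	620	153	112
friend	420	626	493	205	204
trip	430	574	468	270	47
job	398	600	421	291	159
school	553	618	577	198	213
teacher	548	604	560	210	74
summer	465	602	532	214	83
family	455	621	498	203	218
child	566	608	580	176	130
beach	580	577	604	233	40
mountain	589	563	608	245	46
dog	602	621	622	140	120
pet	560	580	565	199	31
day	410	634	420	160	499
year	380	620	390	215	301
time	350	632	360	200	588
home	520	628	540	168	320
town	540	588	550	238	97
place	430	608	440	226	230
little	385	616	420	170	343
young	400	600	430	221	136
old	396	614	425	196	275
small	398	608	418	205	198
tall	470	584	500	229	56
wet	520	590	532	191	44
dry	505	586	510	216	51
open	430	606	450	201	141
full	440	596	452	219	109
happy	405	618	460	172	122
quiet	400	588	420	240	63
warm	492	600	505	200	76
wooden	545	560	538	262	25
pleasant	370	566	395	320	30
falling	460	588	500	190	64
running	480	604	530	175	105
washing	500	592	515	198	43
looking	420	616	450	169	274
stealing	430	556	470	274	19
reaching	425	570	445	251	37
remember	330	610	340	230	140
played	450	600	480	166	96
worked	410	604	420	222	170
traveled	420	560	455	289	27
sang	470	572	505	200	33
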