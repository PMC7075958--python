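# SYNTHETIC demonstration data; generated by scripts/make_demo_data.py
variant	class	severity	allele_freq_pct	source
V4V	silent	silent_control	0.0017	demo
G11G	silent	silent_control	0.001827	demo
D17D	silent	silent_control	0.001964	demo
G24G	silent	silent_control	0.002112	demo
N31N	silent	silent_control	0.00227	demo
P38P	silent	silent_control	0.00244	demo
E44E	silent	silent_control	0.002623	demo
D51D	silent	silent_control	0.002819	demo
P58P	silent	silent_control	0.00303	demo
F64F	silent	silent_control	0.003258	demo
V71V	silent	silent_control	0.003502	demo
T78T	silent	silent_control	0.003764	demo
V84V	silent	silent_control	0.004046	demo
A91A	silent	silent_control	0.004349	demo
M98M	silent	silent_control	0.004675	demo
D105D	silent	silent_control	0.005026	demo
F111F	silent	silent_control	0.005402	demo
Y118Y	silent	silent_control	0.005807	demo
M125M	silent	silent_control	0.006242	demo
I131I	silent	silent_control	0.00671	demo
Y138Y	silent	silent_control	0.007213	demo
L145L	silent	silent_control	0.007753	demo
T152T	silent	silent_control	0.008334	demo
N158N	silent	silent_control	0.008959	demo
F165F	silent	silent_control	0.00963	demo
P172P	silent	silent_control	0.01035	demo
K178K	silent	silent_control	0.01113	demo
N185N	silent	silent_control	0.01196	demo
S192S	silent	silent_control	0.01286	demo
A198A	silent	silent_control	0.01382	demo
R205R	silent	silent_control	0.01486	demo
H212H	silent	silent_control	0.01597	demo
W219W	silent	silent_control	0.01717	demo
Y225Y	silent	silent_control	0.01845	demo
S232S	silent	silent_control	0.01984	demo
T239T	silent	silent_control	0.02132	demo
L245L	silent	silent_control	0.02292	demo
F252F	silent	silent_control	0.02464	demo
I259I	silent	silent_control	0.02648	demo
H266H	silent	silent_control	0.02847	demo
K272K	silent	silent_control	0.0306	demo
V279V	silent	silent_control	0.03289	demo
K286K	silent	silent_control	0.03536	demo
W292W	silent	silent_control	0.03801	demo
M299M	silent	silent_control	0.04086	demo
Q306Q	silent	silent_control	0.04392	demo
Y312Y	silent	silent_control	0.04721	demo
E319E	silent	silent_control	0.05075	demo
T326T	silent	silent_control	0.05455	demo
E333E	silent	silent_control	0.05864	demo
D339D	silent	silent_control	0.06303	demo
P346P	silent	silent_control	0.06776	demo
A353A	silent	silent_control	0.07283	demo
T359T	silent	silent_control	0.07829	demo
V366V	silent	silent_control	0.08416	demo
E373E	silent	silent_control	0.09046	demo
F380F	silent	silent_control	0.09724	demo
A386A	silent	silent_control	0.1045	demo
C393C	silent	silent_control	0.1124	demo
M400M	silent	silent_control	0.1208	demo
P406P	silent	silent_control	0.1298	demo
F413F	silent	silent_control	0.1396	demo
C420C	silent	silent_control	0.15	demo
D426D	silent	silent_control	0.1613	demo
Q433Q	silent	silent_control	0.1733	demo
S440S	silent	silent_control	0.1863	demo
I447I	silent	silent_control	0.2003	demo
L453L	silent	silent_control	0.2153	demo
T460T	silent	silent_control	0.2314	demo
L467L	silent	silent_control	0.2488	demo
L473L	silent	silent_control	0.2674	demo
W480W	silent	silent_control	0.2875	demo
Y487Y	silent	silent_control	0.309	demo
T493T	silent	silent_control	0.3322	demo
I500I	silent	silent_control	0.3571	demo
R507R	silent	silent_control	0.3838	demo
C514C	silent	silent_control	0.4126	demo
G520G	silent	silent_control	0.4435	demo
M527M	silent	silent_control	0.4767	demo
W534W	silent	silent_control	0.5124	demo
T540T	silent	silent_control	0.5508	demo
E547E	silent	silent_control	0.5921	demo
C554C	silent	silent_control	0.6365	demo
V561V	silent	silent_control	0.6842	demo
F567F	silent	silent_control	0.7355	demo
G574G	silent	silent_control	0.7906	demo
N581N	silent	silent_control	0.8498	demo
L587L	silent	silent_control	0.9135	demo
W594W	silent	silent_control	0.9819	demo
H601H	silent	silent_control	1.056	demo
N607N	silent	silent_control	1.135	demo
I614I	silent	silent_control	1.22	demo
K621K	silent	silent_control	1.311	demo
R628R	silent	silent_control	1.409	demo
W634W	silent	silent_control	1.515	demo
W641W	silent	silent_control	1.628	demo
T648T	silent	silent_control	1.75	demo
C654C	silent	silent_control	1.882	demo
M661M	silent	silent_control	2.023	demo
E668E	silent	silent_control	2.174	demo
D675D	silent	silent_control	2.337	demo
D681D	silent	silent_control	2.512	demo
L688L	silent	silent_control	2.7	demo
G695G	silent	silent_control	2.903	demo
R701R	silent	silent_control	3.12	demo
M708M	silent	silent_control	3.354	demo
P715P	silent	silent_control	3.605	demo
V721V	silent	silent_control	3.876	demo
M728M	silent	silent_control	4.166	demo
W735W	silent	silent_control	4.478	demo
D742D	silent	silent_control	4.814	demo
W748W	silent	silent_control	5.175	demo
R755R	silent	silent_control	5.562	demo
A762A	silent	silent_control	5.979	demo
C768C	silent	silent_control	6.427	demo
D775D	silent	silent_control	6.909	demo
R782R	silent	silent_control	7.427	demo
H789H	silent	silent_control	7.983	demo
S795S	silent	silent_control	8.581	demo
H802H	silent	silent_control	9.224	demo
G809G	silent	silent_control	9.915	demo
K815K	silent	silent_control	10.66	demo
R822R	silent	silent_control	11.46	demo
F829F	silent	silent_control	12.32	demo
R835R	silent	silent_control	13.24	demo
N842N	silent	silent_control	14.23	demo
S849S	silent	silent_control	15.3	demo
K856K	silent	silent_control	16.44	demo
R862R	silent	silent_control	17.68	demo
A869A	silent	silent_control	19	demo
C9N	missense	nonpathogenic	0.01	demo
V45E	missense	nonpathogenic	0.01296	demo
E80F	missense	nonpathogenic	0.01678	demo
I116F	missense	nonpathogenic	0.02175	demo
T151K	missense	nonpathogenic	0.02817	demo
S187E	missense	nonpathogenic	0.0365	demo
S222W	missense	nonpathogenic	0.04729	demo
E258D	missense	nonpathogenic	0.06126	demo
C294T	missense	nonpathogenic	0.07937	demo
R329F	missense	nonpathogenic	0.1028	demo
R365A	missense	nonpathogenic	0.1332	demo
M400N	missense	nonpathogenic	0.1726	demo
S436P	missense	nonpathogenic	0.2236	demo
A472Q	missense	nonpathogenic	0.2897	demo
R507D	missense	nonpathogenic	0.3753	demo
V543C	missense	nonpathogenic	0.4862	demo
R578Q	missense	nonpathogenic	0.63	demo
I614D	missense	nonpathogenic	0.8162	demo
W650L	missense	nonpathogenic	1.057	demo
K685R	missense	nonpathogenic	1.37	demo
V721Y	missense	nonpathogenic	1.775	demo
M756I	missense	nonpathogenic	2.299	demo
E792T	missense	nonpathogenic	2.979	demo
F827P	missense	nonpathogenic	3.859	demo
Y863E	missense	nonpathogenic	5	demo
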