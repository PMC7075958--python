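# SYNTHETIC demonstration data; generated by scripts/make_demo_data.py
variant	class	severity	allele_freq_pct	source
L203P	missense	severe_ee		demo
I196F	missense	severe_ee		demo
T197R	missense	severe_ee		demo
W199Y	missense	severe_ee		demo
D200E	missense	severe_ee		demo
K201M	missense	severe_ee		demo
Q204W	missense	severe_ee		demo
R205A	missense	severe_ee		demo
K206S	missense	severe_ee		demo
M208Y	missense	severe_ee		demo
K209W	missense	severe_ee		demo
V210K	missense	severe_ee		demo
Q211G	missense	severe_ee		demo
C213S	missense	uncertain		demo
N214H	missense	uncertain		demo
G215C	missense	uncertain		demo
V217S	missense	mild_bfne		demo
I218H	missense	mild_bfne		demo
L268F	missense	severe_ee		demo
Y265G	missense	severe_ee		demo
H266Q	missense	severe_ee		demo
C269N	missense	severe_ee		demo
Y270M	missense	severe_ee		demo
K272C	missense	severe_ee		demo
F273W	missense	severe_ee		demo
Y274R	missense	severe_ee		demo
M276I	missense	severe_ee		demo
Y277V	missense	severe_ee		demo
M278L	missense	severe_ee		demo
V280W	missense	severe_ee		demo
S281V	missense	uncertain		demo
R282V	missense	uncertain		demo
N284T	missense	mild_bfne		demo
T285D	missense	mild_bfne		demo
W292N	missense	severe_ee		demo
C294T	missense	severe_ee		demo
F295A	missense	severe_ee		demo
K296G	missense	severe_ee		demo
M298L	missense	severe_ee		demo
M299N	missense	severe_ee		demo
R301T	missense	severe_ee		demo
G302K	missense	severe_ee		demo
S303Y	missense	severe_ee		demo
Q305Y	missense	severe_ee		demo
Q306A	missense	severe_ee		demo
R308E	missense	uncertain		demo
D309P	missense	uncertain		demo
P310E	missense	mild_bfne		demo
Y312P	missense	mild_bfne		demo
C94T	missense	mild_bfne		demo
P99Q	missense	mild_bfne		demo
D105K	missense	uncertain		demo
H110V	missense	uncertain		demo
M125T	missense	mild_bfne		demo
K130Y	missense	mild_bfne		demo
C136W	missense	uncertain		demo
A141D	missense	uncertain		demo
I169V	missense	mild_bfne		demo
N174H	missense	mild_bfne		demo
F180G	missense	uncertain		demo
N185V	missense	uncertain		demo
T234N	missense	mild_bfne		demo
T239V	missense	mild_bfne		demo
L245S	missense	uncertain		demo
R250G	missense	uncertain		demo
P315K	missense	mild_bfne		demo
L321N	missense	mild_bfne		demo
T326E	missense	uncertain		demo
L332D	missense	uncertain		demo
Q336M	missense	severe_ee		demo
Y340A	missense	mild_bfne		demo
P344V	missense	mild_bfne		demo
E348P	missense	mild_bfne		demo
K352C	missense	mild_bfne		demo
T356Q	missense	uncertain		demo
D360E	missense	uncertain		demo
T364C	missense	uncertain		demo
E373V	missense	severe_ee		demo
H387R	missense	severe_ee		demo
P401R	missense	mild_bfne		demo
L415del	single_aa_deletion	mild_bfne		demo
D429P	missense	mild_bfne		demo
L443Q	missense	mild_bfne		demo
W457T	missense	uncertain		demo
H471W	missense	uncertain		demo
V485del	single_aa_deletion	uncertain		demo
M499N	missense	uncertain		demo
N513G	missense	uncertain		demo
M527W	missense	uncertain		demo
K552T	missense	severe_ee		demo
R553L	missense	severe_ee		demo
R535M	missense	severe_ee		demo
T537R	missense	severe_ee		demo
S539T	missense	severe_ee		demo
L541N	missense	severe_ee		demo
V543C	missense	severe_ee		demo
A545H	missense	severe_ee		demo
E547N	missense	severe_ee		demo
V549I	missense	mild_bfne		demo
Q555L	missense	uncertain		demo
C557Y	missense	uncertain		demo
R560W	missense	severe_ee		demo
Q562T	missense	severe_ee		demo
R565A	missense	severe_ee		demo
F567P	missense	severe_ee		demo
S570H	missense	severe_ee		demo
G573Y	missense	severe_ee		demo
M576I	missense	severe_ee		demo
P579Q	missense	severe_ee		demo
N581Q	missense	severe_ee		demo
E584K	missense	uncertain		demo
L587V	missense	uncertain		demo
W594Q	missense	mild_bfne		demo
V605del	single_aa_deletion	uncertain		demo
H615D	missense	uncertain		demo
R835M	missense	mild_bfne		demo
Q851del	single_aa_deletion	uncertain		demo
L20M	missense	mild_bfne		demo
V45E	missense	severe_ee		demo
M60N	missense	mild_bfne		demo
Q70F	missense	severe_ee		demo
E85L	missense	mild_bfne		demo
K115F	missense	mild_bfne		demo
D150Q	missense	mild_bfne		demo
H190V	missense	uncertain		demo
Y225G	missense	uncertain		demo
W650L	missense	uncertain		demo
I700K	missense	uncertain		demo
F750S	missense	uncertain		demo
Y865G	missense	uncertain		demo
H110*	nonsense	severe_ee		demo
F140*	nonsense	severe_ee		demo
C175*	nonsense	uncertain		demo
C213*	nonsense	severe_ee		demo
T240*	nonsense	severe_ee		demo
Y270*	nonsense	severe_ee		demo
Y300*	nonsense	severe_ee		demo
P450*	nonsense	uncertain		demo
I550*	nonsense	severe_ee		demo
I600*	nonsense	mild_bfne		demo
fs_01	frameshift	severe_ee		demo
fs_02	frameshift	severe_ee		demo
fs_03	frameshift	severe_ee		demo
fs_04	frameshift	severe_ee		demo
fs_05	frameshift	severe_ee		demo
fs_06	frameshift	severe_ee		demo
fs_07	frameshift	severe_ee		demo
fs_08	frameshift	severe_ee		demo
fs_09	frameshift	severe_ee		demo
fs_10	frameshift	severe_ee		demo
fs_11	frameshift	severe_ee		demo
fs_12	frameshift	severe_ee		demo
fs_13	frameshift	uncertain		demo
fs_14	frameshift	uncertain		demo
fs_15	frameshift	uncertain		demo
fs_16	frameshift	uncertain		demo
fs_17	frameshift	uncertain		demo
fs_18	frameshift	uncertain		demo
fs_19	frameshift	uncertain		demo
fs_20	frameshift	uncertain		demo
fs_21	frameshift	mild_bfne		demo
fs_22	frameshift	mild_bfne		demo
fs_23	frameshift	mild_bfne		demo
fs_24	frameshift	mild_bfne		demo
fs_25	frameshift	mild_bfne		demo
splice_01	splice_site	severe_ee		demo
splice_02	splice_site	severe_ee		demo
splice_03	splice_site	severe_ee		demo
splice_04	splice_site	severe_ee		demo
splice_05	splice_site	severe_ee		demo
splice_06	splice_site	severe_ee		demo
splice_07	splice_site	uncertain		demo
splice_08	splice_site	uncertain		demo
splice_09	splice_site	uncertain		demo
splice_10	splice_site	uncertain		demo
splice_11	splice_site	uncertain		demo
splice_12	splice_site	uncertain		demo
splice_13	splice_site	mild_bfne		demo
splice_14	splice_site	mild_bfne		demo
splice_15	splice_site	mild_bfne		demo
splice_16	splice_site	mild_bfne		demo
splice_17	splice_site	mild_bfne		demo
gene_del_01	gene_deletion	severe_ee		demo
gene_del_02	gene_deletion	severe_ee		demo
gene_del_03	gene_deletion	severe_ee		demo
gene_del_04	gene_deletion	severe_ee		demo
gene_del_05	gene_deletion	severe_ee		demo
gene_del_06	gene_deletion	uncertain		demo
gene_del_07	gene_deletion	uncertain		demo
gene_del_08	gene_deletion	uncertain		demo
gene_del_09	gene_deletion	mild_bfne		demo
gene_del_10	gene_deletion	mild_bfne		demo
M1V	non_initiation	uncertain		demo
M1T	non_initiation	uncertain		demo
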