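>KCNQ2_SYNTHETIC_DEMO synthetic Kv7.2-style reference, 872 aa
MPQVNSTFCHGVWALTDSDLTHHGRGYKLMNNMYTSRPHYLFTEVPDAKADMYLTWTPKM
GLIFYACEYQVFRILAPTQEMGYVEMWTRPARLCFMRMPVQIPNDCQINHFEITKINYIN
KPKPMQYENKIFCKTCKYYFAQAHLVCQMDTTLWPWYNGDNESWFNAEIVYPNNCIYKFF
RAYVNLSMLHKSCARITAWDKYLQRKCMKVQHCNGQVIWMMSSWYEKWHANSRTPDTKTT
YAVPLSYMCRFFEEWIDEIHHWVNYHDLCYFKFYEMYMVVSRNNTKWVIKRWCCFKEMMY
RGSTQQHRDPWYGHPIRFECLFGWTTNDRPWLENLQIHDYSLFPKPCERCQKASQTVRTD
WWQTRVVMTWGAEAKAGGRFWEYNFAHNDEDQCALHNWVMPTKQFPFESNIAFTLYWVAC
NHTHEDHPDSHHQVKSHDTSSVLENNIPGPSCLQCPWTQTIHCRHVLVDEHALQQFENPW
VIEGVLYQNDNITDEQQTMIHIQMGFRFFHVLNCHSSNVGECESWDMDTDPCRWRGTHST
LPVEAKEVVIHKRCQRCSMRVQHIRCFMWSTEGGRMFRPVNDVECSLPDRKYPWSTCSPI
HPEEVSNSHRFKDIHKLAHTKMDIYMARSIATGWIISDASWYDDHRWTIWGDKCQYDDEE
MNYKWSVELWSFTSDCGLEADHIHKRFLRCWYGVGWQFCIRFMDKAYMTDEENVPLWEEQ
VGGMSGTMRPLMYIWSEVIEGDHDMYYWFFQYTFRMKLMWSASHHNYCMFWLVVDSSTYS
TRGTRQYRHHHECSSEIWTNYHTWNEGMGCEYINKTDGNTLRTPTYFKFKAQFTRHLQKF
ANMSDCRRSAQYSLLKCRMMWRYCYNKNAWPA
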