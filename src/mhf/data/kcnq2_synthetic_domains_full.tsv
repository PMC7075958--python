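# SYNTHETIC demonstration data; generated by scripts/make_demo_data.py
name	start	end
S1	92	112
S2	123	143
S3	167	187
S4	196	218
S5	232	252
pore_loop	265	285
S6	292	312
pre_helix_A	313	334
helix_A	335	365
helix_A_B_linker	366	534
helix_B	535	557
helix_B_C_linker	558	588
helix_C	589	620
helix_D	828	858
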