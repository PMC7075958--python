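# SYNTHETIC demonstration data; generated by scripts/make_demo_data.py
name	start	end
pre_helix_A	313	334
helix_A	335	365
helix_A_B_linker	366	534
helix_B	535	557
helix_B_C_linker	558	588
helix_C	589	620
helix_C_D_linker	621	827
helix_D	828	858
distal_C_terminus	859	872
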