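condition	aba_ng_per_g_fw
control_1	304
drought	14991
control_2	158
rehydration	1913
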