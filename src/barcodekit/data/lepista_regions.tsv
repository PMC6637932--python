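region	length_min	length_max	n_total	n_pcr_success
ITS	605	615	34	34
IGS	415	440	34	34
nLSU	934	939	34	33
mtSSU	662	740	34	32
tef1	861	920	34	23
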