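# Wireless 4-optode headband, 4 Hz (in-flight sessions)
n_optodes: 4
fs_hz: 4.0
wavelengths_nm: [730, 850]
separation_mm: 25.0
dpf: 5.97
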