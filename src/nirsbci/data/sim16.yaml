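# Desktop 16-optode headband, 2 Hz (simulator sessions)
n_optodes: 16
fs_hz: 2.0
wavelengths_nm: [730, 850]
separation_mm: 25.0
dpf: 5.97
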