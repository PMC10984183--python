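group,a0b0,a1b0,a0b1,a1b1
cases,3,8,6,225
controls,20,18,12,166
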