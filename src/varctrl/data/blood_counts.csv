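group,value
Control,7.40
Control,8.50
Control,7.20
Control,8.24
Control,9.84
Control,8.32
Drug A,9.76
Drug A,8.80
Drug A,7.68
Drug A,9.36
Drug B,12.80
Drug B,9.68
Drug B,12.16
Drug B,9.20
Drug B,10.55
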