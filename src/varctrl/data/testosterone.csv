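group,value
Non-smokers,0.32
Non-smokers,0.43
Non-smokers,0.99
Non-smokers,0.95
Non-smokers,0.92
Non-smokers,0.56
Non-smokers,0.87
Non-smokers,0.64
Non-smokers,0.78
Non-smokers,0.72
Former smokers,0.36
Former smokers,0.93
Former smokers,0.40
Former smokers,0.86
Former smokers,0.85
Former smokers,0.51
Former smokers,0.76
Former smokers,0.58
Former smokers,0.73
Former smokers,0.65
Light smokers,0.82
Light smokers,0.37
Light smokers,0.77
Light smokers,0.42
Light smokers,0.74
Light smokers,0.44
Light smokers,0.48
Light smokers,0.51
Light smokers,0.61
Light smokers,0.60
Heavy smokers,0.29
Heavy smokers,0.53
Heavy smokers,0.33
Heavy smokers,0.34
Heavy smokers,0.52
Heavy smokers,0.50
Heavy smokers,0.49
Heavy smokers,0.47
Heavy smokers,0.40
Heavy smokers,0.45
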