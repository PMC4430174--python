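# Synthetic month-24 GA area distribution, mm^2 (n=19; mean 1.10, range 0.14-2.58)
2.58
2.58
2.58
2.58
2.58
2.58
1.98
0.30
0.30
0.30
0.30
0.30
0.30
0.30
0.30
0.30
0.30
0.30
0.14
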