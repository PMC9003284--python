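alternative,precision,recall,f1_score
Zhu,0.9632,0.8651,0.8681
Shi15,0.7664,0.9985,0.8653
Shi14,0.8001,0.9531,0.8112
Su,0.7645,0.9644,0.7997
Zhuo,0.6788,1,0.7667
Zeng,0.9886,1,0.9895
LBP,0.8631,0.9651,0.8697
LTP,0.9981,0.9564,0.9811
Basar21,0.9785,1,0.9885
Ours,0.9894,1,0.9990
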