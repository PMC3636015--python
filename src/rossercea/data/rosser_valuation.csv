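disability,A,B,C,D
I,1.000,0.995,0.990,0.967
II,0.990,0.986,0.973,0.932
III,0.980,0.972,0.956,0.912
IV,0.964,0.956,0.942,0.870
V,0.946,0.935,0.900,0.700
VI,0.875,0.845,0.680,0.000
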