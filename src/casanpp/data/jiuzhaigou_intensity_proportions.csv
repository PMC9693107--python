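period,zone,b1,b2,b3,b4,b5
dur_quake,VII-VIII,1.93,15.28,78.99,3.26,0.54
dur_quake,VIII-IX,0.97,12.49,84.98,1.53,0.03
dur_quake,IX+,1.86,3.26,5.21,87.81,1.86
dur_quake,VII-IX+,1.21,13.23,83.53,1.81,0.22
post_quake,VII-VIII,1.20,2.76,24.03,67.70,4.31
post_quake,VIII-IX,0.03,0.29,5.66,91.33,2.69
post_quake,IX+,1.02,2.05,3.07,92.47,1.40
post_quake,VII-IX+,0.39,1.32,13.38,82.23,2.68
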