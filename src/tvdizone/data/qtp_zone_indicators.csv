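zone,TVDI-Max,TVDI-Min,TVDI-Mean,TVDI-SD,Slope-Mean,TVDI-t3,TVDI-t4,TVDI-t5,TVDI-t6
AQM,1.00,0.00,0.55,0.24,3.75,47.34%,44.11%,6.19%,2.37%
QHB,0.97,0.01,0.66,0.20,1.04,42.64%,51.48%,4.07%,1.82%
KWKM,1.00,0.00,0.55,0.18,1.09,20.64%,69.28%,8.21%,1.87%
CEKM,1.00,0.00,0.54,0.21,1.54,25.59%,62.20%,9.96%,2.25%
QP,0.99,0.00,0.59,0.15,5.94,46.76%,42.58%,6.96%,3.70%
STR,0.94,0.00,0.50,0.10,9.69,41.10%,46.45%,8.04%,4.41%
HMLY,1.00,0.03,0.59,0.18,-3.43,58.71%,37.09%,3.41%,0.79%
HDM,1.00,0.00,0.52,0.15,-1.83,73.79%,24.25%,1.57%,0.40%
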