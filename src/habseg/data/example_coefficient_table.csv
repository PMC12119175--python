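variable,stratum,species,beta,se,partial_r2_pct
dwat,LOW,af,-3.76,1.53,8.2
hcov,LOW,af,-0.64,0.2,4.9
rocks,LOW,af,0,0,0
con,LOW,af,0,0,0
tcov,LOW,af,0,0,0
moist,LOW,af,0.54,0.32,3.1
scov,LOW,af,0,0,0
hheight,LOW,af,0,0,0
logs,LOW,af,0,0,0
dwat,LOW,cg,0,0,0
hcov,LOW,cg,0.38,0.12,2.5
rocks,LOW,cg,0,0,0
con,LOW,cg,0.19,0.23,<1
tcov,LOW,cg,2.98,0.75,69.4
moist,LOW,cg,-1.07,0.17,4.1
scov,LOW,cg,0,0,0
hheight,LOW,cg,0,0,0
logs,LOW,cg,0.05,0.12,1.2
dwat,HIGH,af,-0.18,0.14,4.2
hcov,HIGH,af,-0.13,0.5,2
rocks,HIGH,af,0.54,0.21,<1
con,HIGH,af,1.4,1.54,1.6
tcov,HIGH,af,-0.72,1.17,1.2
moist,HIGH,af,0.40,0.15,2
scov,HIGH,af,-0.73,0.51,2.1
hheight,HIGH,af,-0.32,0.26,<1
logs,HIGH,af,-0.6,0.36,<1
dwat,HIGH,cg,0.61,0.37,1.3
hcov,HIGH,cg,0,0,0
rocks,HIGH,cg,0.59,0.35,6.3
con,HIGH,cg,1.52,0.52,34.6
tcov,HIGH,cg,0.93,0.35,33.5
moist,HIGH,cg,-0.61,0.36,<1
scov,HIGH,cg,-0.96,0.56,1.9
hheight,HIGH,cg,1.3,0.73,<1
logs,HIGH,cg,0,0,0
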