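variant,state,E_tot,x1,x2,x3,E1,E2,E3,mu1,mu2,mu3,E_sum,RMSD_pct
Y165oCNF,Pfr,-53.41,0.25,0.75,,-32.09,-81.68,,5.948,8.279,,-69.40,29.93
Y165oCNF,Lumi-F,-52.13,0.44,0.56,,-27.61,-95.34,,5.738,8.921,,-65.58,25.82
Y165oCNF,Meta-F,-48.30,0.95,0.05,,-33.96,-347.8,,6.036,20.785,,-49.07,1.58
Y165oCNF,Pr,-53.33,0.88,0.12,,-28.36,-252.7,,5.773,16.318,,-54.37,1.95
F192oCNF,Pfr,-45.40,0.81,0.19,,-29.48,-66.8,,5.826,7.580,,-36.54,19.52
F192oCNF,Lumi-F,-44.39,0.77,0.23,,-29.48,-57.78,,5.826,7.156,,-36.01,18.89
F192oCNF,Meta-F,-20.17,1.0,,,-28.36,,,5.220,,,-28.36,40.60
F192oCNF,Pr,-52.59,0.74,0.26,,-30.60,-74.81,,5.878,7.956,,-41.92,20.29
Y165pCNF,Pfr,-73.84,,1.00,,,-53.70,,,9.564,,-53.70,27.27
Y165pCNF,Lumi-F,-221.70,,1.00,,,-161.23,,,14.618,,-161.23,27.27
Y165pCNF,Meta-F,-33.44,,1.00,,,-24.32,,,8.183,,-24.32,27.27
Y165pCNF,Pr,-128.72,,0.36,0.64,,-152.16,-53.40,,14.192,9.550,-88.96,30.89
F192pCNF,Pfr,-28.76,0.24,0.76,,-35.82,-38.74,,8.724,8.861,,-38.05,32.30
F192pCNF,Lumi-F,-20.56,0.38,0.62,,-34.33,-22.75,,8.654,8.109,,-27.12,31.89
F192pCNF,Meta-F,-29.50,0.40,0.60,,-35.07,-41.61,,8.688,8.996,,-39.02,32.26
F192pCNF,Pr,-41.32,0.19,0.81,,-33.58,-59.19,,8.618,9.822,,-54.44,31.76
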