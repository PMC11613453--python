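variant,state,E_sum,x1,E1,x2,E2,E2_non,E2_HB,x3,E3,E3_non,E3_HB,E_tot_non,E_tot_HB
Y165oCNF,Pfr,-69.40,0.25,-32.09,0.75,-81.68,-43.67,-38.01,,,,,-40.80,-28.60
Y165oCNF,Lumi-F,-65.58,0.44,-27.61,0.56,-95.34,-48.86,-46.48,,,,,-39.53,-26.06
Y165oCNF,Meta-F,-49.07,0.95,-33.96,0.05,-347.8,-159.52,-188.25,,,,,-40.00,-9.06
Y165oCNF,Pr,-54.37,0.88,-28.36,0.12,-252.7,-115.48,-137.25,,,,,-38.46,-15.91
F192oCNF,Pfr,-36.54,0.81,-29.48,0.19,-66.8,-34.32,-32.49,,,,,-30.40,-6.14
F192oCNF,Lumi-F,-36.01,0.77,-29.48,0.23,-57.78,-30.67,-27.10,,,,,-29.76,-6.25
F192oCNF,Meta-F,-28.36,1.0,-28.36,,,,,,,,,-28.36,0.0
F192oCNF,Pr,-41.92,0.74,-30.60,0.26,-74.81,-38.38,-36.43,,,,,-32.59,-9.33
Y165pCNF,Pfr,-53.70,,,1.00,-53.70,-16.75,-36.95,,,,,-16.75,-36.95
Y165pCNF,Lumi-F,-161.23,,,1.00,-161.23,-68.48,-92.76,,,,,-68.48,-92.76
Y165pCNF,Meta-F,-24.32,,,1.00,-24.32,-3.13,-21.19,,,,,-3.13,-21.19
Y165pCNF,Pr,-88.96,,,0.36,-152.16,-69.51,-82.65,0.64,-53.40,-7.65,-45.75,-29.92,-59.04
F192pCNF,Pfr,-38.05,0.24,-35.82,0.76,-38.74,-25.10,-13.64,,,,,-27.65,-10.40
F192pCNF,Lumi-F,-27.12,0.38,-34.33,0.62,-22.75,-17.63,-5.12,,,,,-23.92,-3.19
F192pCNF,Meta-F,-39.02,0.40,-35.07,0.60,-41.61,-25.69,-15.92,,,,,-29.41,-9.61
F192pCNF,Pr,-54.44,0.19,-33.58,0.81,-59.19,-37.05,-22.14,,,,,-36.40,-18.03
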