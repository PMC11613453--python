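variant,state,T_K,role,nu_T,nu_RT,I_T,I_RT,mu,hbond
Y165oCNF,Pfr,300,env,,,7.64,7.64,7.767,
Y165oCNF,Pfr,300,P1,2225.9,2225.9,1.11,1.11,2.960,False
Y165oCNF,Pfr,300,P2,2230.4,2230.4,6.5,6.5,7.181,True
Y165oCNF,Lumi-F,300,env,,,7.484,7.484,7.687,
Y165oCNF,Lumi-F,300,P1,2227.1,2227.1,1.832,1.832,3.802,False
Y165oCNF,Lumi-F,300,P2,2230.7,2230.7,5.652,5.652,6.680,True
Y165oCNF,Meta-F,300,env,,,7.028,7.028,7.449,
Y165oCNF,Meta-F,300,P1,2225.4,2225.4,4.392,4.392,5.889,False
Y165oCNF,Meta-F,300,P2,2229.4,2229.4,2.635,2.635,4.561,True
Y165oCNF,Pr,300,env,,,7.63,7.63,7.762,
Y165oCNF,Pr,300,P1,2226.9,2226.9,3.72,3.72,5.428,False
Y165oCNF,Pr,300,P2,2231.0,2231.0,3.91,3.91,5.556,True
F192oCNF,Pfr,300,env,,,12.86,12.86,6.196,
F192oCNF,Pfr,300,P1,2226.6,2226.6,9.22,9.22,5.246,False
F192oCNF,Pfr,300,P2,2231.8,2231.8,3.64,3.64,3.296,True
F192oCNF,Lumi-F,300,env,,,12.70,12.70,6.157,
F192oCNF,Lumi-F,300,P1,2226.6,2226.6,8.746,8.746,5.110,False
F192oCNF,Lumi-F,300,P2,2231.7,2231.7,3.955,3.955,3.436,True
F192oCNF,Meta-F,300,env,,,9.130,9.130,5.220,
F192oCNF,Meta-F,300,P1,2226.9,2226.9,9.130,9.130,5.220,False
F192oCNF,Pr,300,env,,,14.04,14.04,6.474,
F192oCNF,Pr,300,P1,2226.3,2226.3,8.61,8.61,5.070,False
F192oCNF,Pr,300,P2,2231.5,2231.5,5.43,5.43,4.026,True
Y165pCNF,Pfr,300,env,,,2.642,2.642,9.564,
Y165pCNF,Pfr,300,P2,2237.4,2237.4,2.642,2.642,9.564,True
Y165pCNF,Lumi-F,300,env,,,6.172,6.172,14.618,
Y165pCNF,Lumi-F,300,P2,2234.7,2234.7,6.172,6.172,14.618,True
Y165pCNF,Meta-F,300,env,,,1.934,1.934,8.183,
Y165pCNF,Meta-F,300,P2,2237.9,2237.9,1.934,1.934,8.183,True
Y165pCNF,Pr,300,env,,,3.780,3.780,11.44,
Y165pCNF,Pr,300,P2,2232.4,2232.4,2.094,2.094,8.515,True
Y165pCNF,Pr,300,P3,2241.6,2241.6,1.686,1.686,7.640,True
F192pCNF,Pfr,300,env,,,1.516,1.516,8.829,
F192pCNF,Pfr,300,P1,2224.9,2224.9,0.352,0.352,4.254,False
F192pCNF,Pfr,300,P2,2230.5,2230.5,1.164,1.164,7.736,True
F192pCNF,Lumi-F,300,env,,,1.346,1.346,8.319,
F192pCNF,Lumi-F,300,P1,2225.3,2225.3,0.549,0.549,5.313,False
F192pCNF,Lumi-F,300,P2,2230.8,2230.8,0.797,0.797,6.401,True
F192pCNF,Meta-F,300,env,,,1.532,1.532,8.875,
F192pCNF,Meta-F,300,P1,2225.1,2225.1,0.582,0.582,5.470,False
F192pCNF,Meta-F,300,P2,2230.8,2230.8,0.950,0.950,6.989,True
F192pCNF,Pr,300,env,,,1.796,1.796,9.610,
F192pCNF,Pr,300,P1,2225.5,2225.5,0.268,0.268,3.712,False
F192pCNF,Pr,300,P2,2229.0,2229.0,1.528,1.528,8.864,True
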