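component,J_s,J_s_se,kappa,kappa_se,kappa_theta,kappa_theta_se,gamma_bend_pN,gamma_bend_se
POPC,-0.001,0.028,33.7,1.4,42.53,1.7,62,4
POPE,-0.178,0.005,48.0,0.9,65.6,2.9,130,3
POPA,0.027,0.006,53.1,2.3,72.1,2.7,86,4
POPI,0.172,0.016,42.8,2.1,55.8,2.6,44,3
POPG,0.227,0.017,30.2,1.3,35.8,1.6,32,2
POPS,-0.019,0.007,50.3,2.3,78,4,91,5
POPC:LPC 80:20,0.085,0.008,28.2,1.2,32.6,1.4,43,2
POPC:OA 80:20,-0.063,0.009,37.7,1.5,58.8,2.5,81,4
POPC:CHOL 70:30,-0.0007,0.003,105,5,166,8,160,8
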