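species,epsilon,se_epsilon,rho,se_rho,theta,se_theta,rmse_cm,n
All,3.139,0.219,0.715,0.026,0.014,0.002,11.0,1762
Abies alba,0.503,0.299,1.287,0.219,0.008,0.006,8.6,70
Angiosperms,3.745,1.640,0.631,0.181,0.008,0.014,8.2,26
Larix decidua,4.695,0.447,0.553,0.041,0.021,0.004,9.8,473
Picea abies,2.102,0.289,0.848,0.047,0.011,0.002,11.1,1174
Pinus cembra,1.362,3.668,1.303,1.119,0.001,0.017,12.9,19
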