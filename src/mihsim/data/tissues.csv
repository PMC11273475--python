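tissue,sigma_S_per_m,eps_r,rho_kg_m3,c_J_kgK,k_W_mK,omega_b_per_s,Qm_W_m3
scalp,0.000451,1120,1109,3391,0.37,0.02,1620
torso,0.304169,5411.25,,,,,
limbs,0.27945,3670,,,,,
skull,0.0208,228,1908,1313,0.32,0.000436,610
brain tissue,0.1079,2665,1043,3639.5,0.515,0.00883,7100
muscle,0.362,8090,1090,3421,0.49,0.00869,480
magnetic nanofluids,,,5180,4000,40,,
tumor tissue,,,1060,3650,0.535,0.01392,5790
mixed tissue,,,1072.4,3651.1,0.5316,,
air,0,1,,,,,
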