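compound_id,term,mean,sd
8012-0567,e_ele,-48.00,5.58
8012-0567,e_vdw,-43.96,2.53
8012-0567,e_ele_sol,54.42,3.89
8012-0567,e_nonpl_sol,-5.33,0.11
8012-0567,dh,-42.88,2.84
8018-7603,e_ele,-41.18,10.34
8018-7603,e_vdw,-43.62,2.95
8018-7603,e_ele_sol,54.53,7.34
8018-7603,e_nonpl_sol,-5.69,0.18
8018-7603,dh,-35.96,3.68
8018-7168,e_ele,-25.15,5.51
8018-7168,e_vdw,-46.63,2.98
8018-7168,e_ele_sol,38.43,3.74
8018-7168,e_nonpl_sol,-6.08,0.14
8018-7168,dh,-39.44,2.93
8018-6529,e_ele,-24.84,4.16
8018-6529,e_vdw,-44.75,2.67
8018-6529,e_ele_sol,40.04,2.97
8018-6529,e_nonpl_sol,-5.82,0.12
8018-6529,dh,-35.36,2.65
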