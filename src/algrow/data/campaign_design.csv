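experiment,t_cyc_d,c_x0_gpl,pr_data_gpld,a_gpl_per_au,b_gpl,r2
01,3.4,0.89,0.36,0.100,-1.241,1.00
02,3.4,0.74,0.36,0.092,-1.067,1.00
03,3.0,0.78,0.38,0.114,-1.816,1.00
04,2.9,1.03,0.34,0.108,-1.719,1.00
05,3.5,0.81,0.35,0.111,-1.864,1.00
06,7.0,0.27,0.29,0.101,-1.650,0.99
07,2.0,0.53,0.34,0.136,-2.965,0.97
08,3.7,0.81,0.34,0.101,-1.058,1.00
09,0.7,0.98,0.25,0.225,-3.992,1.00
10,3.4,0.63,0.38,0.094,-1.071,1.00
11,2.7,0.96,0.28,0.095,-0.985,1.00
12,7.0,0.46,0.31,0.094,-0.796,0.99
13,7.0,0.48,0.29,0.090,-0.723,0.99
14,7.0,0.43,0.32,0.103,-1.278,0.98
15,6.2,0.66,0.34,0.103,-1.310,0.98
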