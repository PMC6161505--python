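case,d_design_um,dprime_design_um,s_design_um,d_meas_um,d_meas_sd,dprime_meas_um,dprime_meas_sd,s_meas_um,s_meas_sd,porosity_pct
1,8,6.93,4,7.51,0.13,6.50,0.11,4.46,0.09,40.19
2,10,8.66,4,9.13,0.09,7.90,0.08,4.69,0.24,46.79
3,12,10.40,4,11.21,0.11,9.71,0.10,4.77,0.15,52.14
4,15,12.99,4,14.52,0.20,12.57,0.17,4.43,0.06,58.46
5,12,10.40,2,11.42,0.17,9.89,0.15,2.46,0.11,70.33
6,100,86.60,4,99.35,0.50,86.04,0.43,4.48,0.11,91.37
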