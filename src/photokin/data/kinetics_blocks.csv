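condition,lamp,ph,k0_per_min,k2_m_min,phi
aerobic,visible,2.0,0.0014,1.45,0.59
aerobic,visible,3.0,0.0036,2.18,0.94
aerobic,visible,4.0,0.0024,1.44,0.62
aerobic,visible,5.0,0.0065,0.77,0.31
aerobic,visible,6.0,0.0078,0.74,0.32
aerobic,visible,7.0,0.0014,1.37,0.61
aerobic,visible,8.0,0.002,2.93,1.19
aerobic,visible,9.0,0.0029,4.51,1.81
aerobic,visible,10.0,0.0052,6.27,2.53
aerobic,visible,11.0,0.011,7.25,3.07
aerobic,visible,12.0,0.0111,8.22,3.46
aerobic,uv,2.0,0.0006,0.61,0.58
aerobic,uv,3.0,0.0014,0.92,0.93
aerobic,uv,4.0,0.001,0.6,0.61
aerobic,uv,5.0,0.0002,0.32,0.31
aerobic,uv,6.0,0.0004,0.33,0.32
aerobic,uv,7.0,0.0007,0.59,0.6
aerobic,uv,8.0,0.0011,1.23,1.18
aerobic,uv,9.0,0.0016,1.89,1.8
aerobic,uv,10.0,0.0024,2.6,2.52
aerobic,uv,11.0,0.0042,3.04,3.05
aerobic,uv,12.0,0.0046,3.23,3.24
anaerobic,visible,2.0,0.00016,0.145,0.059
anaerobic,visible,3.0,0.00037,0.218,0.094
anaerobic,visible,4.0,0.00025,0.144,0.062
anaerobic,visible,5.0,6e-05,0.077,0.031
anaerobic,visible,6.0,0.0001,0.074,0.031
anaerobic,visible,7.0,0.00021,0.14,0.061
anaerobic,visible,8.0,0.00032,0.293,0.119
anaerobic,visible,9.0,0.00042,0.45,0.181
anaerobic,visible,10.0,0.00059,0.627,0.253
anaerobic,visible,11.0,0.00095,0.725,0.307
anaerobic,visible,12.0,0.00102,0.805,0.337
anaerobic,uv,2.0,5e-05,0.061,0.058
anaerobic,uv,3.0,0.00015,0.092,0.093
anaerobic,uv,4.0,9e-05,0.06,0.146
anaerobic,uv,5.0,2e-05,0.032,0.03
anaerobic,uv,6.0,3e-05,0.031,0.031
anaerobic,uv,7.0,6e-05,0.059,0.06
anaerobic,uv,8.0,0.00012,0.123,0.118
anaerobic,uv,9.0,0.00025,0.187,0.178
anaerobic,uv,10.0,0.00036,0.258,0.252
anaerobic,uv,11.0,0.00045,0.308,0.305
anaerobic,uv,12.0,0.00048,0.321,0.322
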