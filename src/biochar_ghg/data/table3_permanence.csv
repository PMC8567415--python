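soil_temp_c,timeframe_years,fperm_low,fperm_low_se,fperm_medium,fperm_medium_se,fperm_high,fperm_high_se,c_hc,m_hc,r2
5.0,100,0.84,0.037,0.89,0.018,0.94,0.0086,1.13,-0.46,0.31
10.0,100,0.72,0.042,0.79,0.026,0.88,0.019,1.10,-0.59,0.33
15.0,100,0.63,0.045,0.71,0.03,0.82,0.028,1.04,-0.64,0.32
20.0,100,0.57,0.047,0.67,0.032,0.79,0.033,1.01,-0.65,0.31
25.0,100,0.54,0.049,0.64,0.033,0.76,0.037,0.98,-0.66,0.30
10.9,100,0.7,0.042,0.77,0.027,0.87,0.021,1.09,-0.60,0.33
14.9,100,0.63,0.045,0.71,0.03,0.82,0.028,1.04,-0.64,0.32
5.0,500,0.55,0.048,0.66,0.032,0.78,0.037,0.99,-0.65,0.30
10.0,500,0.3,0.052,0.44,0.035,0.57,0.061,0.74,-0.60,0.23
15.0,500,0.19,0.05,0.32,0.033,0.44,0.071,0.57,-0.49,0.17
20.0,500,0.15,0.049,0.26,0.031,0.37,0.074,0.48,-0.43,0.13
25.0,500,0.13,0.049,0.23,0.03,0.34,0.075,0.43,-0.39,0.12
10.9,500,0.27,0.052,0.41,0.035,0.54,0.064,0.71,-0.58,0.21
14.9,500,0.19,0.05,0.32,0.033,0.44,0.071,0.57,-0.50,0.17
5.0,1000,0.35,0.051,0.49,0.034,0.63,0.058,0.80,-0.62,0.24
10.0,1000,0.14,0.049,0.25,0.031,0.37,0.075,0.47,-0.42,0.13
15.0,1000,0.083,0.048,0.16,0.026,0.25,0.073,0.30,-0.27,0.07
20.0,1000,0.066,0.047,0.12,0.023,0.2,0.069,0.23,-0.21,0.04
25.0,1000,0.06,0.047,0.1,0.021,0.17,0.066,0.20,-0.17,0.03
10.9,1000,0.12,0.049,0.23,0.03,0.34,0.075,0.43,-0.38,0.12
14.9,1000,0.084,0.048,0.16,0.026,0.25,0.073,0.30,-0.28,0.07
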