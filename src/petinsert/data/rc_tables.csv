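algorithm,metric,arm,sphere_mm,sbr,rc_avg,rc_sd
OSEM,mean,experimental,13,2.07,0.67,0.04
OSEM,mean,experimental,13,3.93,0.65,0.02
OSEM,mean,experimental,13,6.03,0.64,0.01
OSEM,mean,experimental,13,7.97,0.6,0.01
OSEM,mean,experimental,10,2.07,0.65,0.03
OSEM,mean,experimental,10,3.93,0.58,0.02
OSEM,mean,experimental,10,6.03,0.57,0.02
OSEM,mean,experimental,10,7.97,0.56,0.01
OSEM,mean,experimental,8,2.07,0.56,0.04
OSEM,mean,experimental,8,3.93,0.45,0.03
OSEM,mean,experimental,8,6.03,0.47,0.01
OSEM,mean,experimental,8,7.97,0.45,0.01
OSEM,mean,experimental,6,2.07,0.43,0.06
OSEM,mean,experimental,6,3.93,0.46,0.01
OSEM,mean,experimental,6,6.03,0.4,0.01
OSEM,mean,experimental,6,7.97,0.36,0.03
OSEM,mean,experimental,5,2.07,0.42,0.08
OSEM,mean,experimental,5,3.93,0.32,0.06
OSEM,mean,experimental,5,6.03,0.3,0.02
OSEM,mean,experimental,5,7.97,0.29,0.05
OSEM,mean,experimental,4,2.07,0.42,0.14
OSEM,mean,experimental,4,3.93,0.29,0.03
OSEM,mean,experimental,4,6.03,0.32,0.05
OSEM,mean,experimental,4,7.97,0.24,0.05
OSEM,mean,simulated,13,2.07,0.71,0.03
OSEM,mean,simulated,13,3.93,0.66,0.02
OSEM,mean,simulated,13,6.03,0.64,0.01
OSEM,mean,simulated,13,7.97,0.63,0.01
OSEM,mean,simulated,10,2.07,0.69,0.04
OSEM,mean,simulated,10,3.93,0.63,0.02
OSEM,mean,simulated,10,6.03,0.61,0.02
OSEM,mean,simulated,10,7.97,0.6,0.01
OSEM,mean,simulated,8,2.07,0.58,0.04
OSEM,mean,simulated,8,3.93,0.53,0.03
OSEM,mean,simulated,8,6.03,0.51,0.03
OSEM,mean,simulated,8,7.97,0.5,0.02
OSEM,mean,simulated,6,2.07,0.49,0.05
OSEM,mean,simulated,6,3.93,0.43,0.03
OSEM,mean,simulated,6,6.03,0.4,0.02
OSEM,mean,simulated,6,7.97,0.38,0.02
OSEM,mean,simulated,5,2.07,0.45,0.06
OSEM,mean,simulated,5,3.93,0.35,0.04
OSEM,mean,simulated,5,6.03,0.31,0.02
OSEM,mean,simulated,5,7.97,0.3,0.02
OSEM,mean,simulated,4,2.07,0.4,0.06
OSEM,mean,simulated,4,3.93,0.31,0.06
OSEM,mean,simulated,4,6.03,0.26,0.05
OSEM,mean,simulated,4,7.97,0.23,0.04
OSEM,max,experimental,13,2.07,1.67,0.29
OSEM,max,experimental,13,3.93,1.22,0.02
OSEM,max,experimental,13,6.03,1.12,0.02
OSEM,max,experimental,13,7.97,0.99,0.03
OSEM,max,experimental,10,2.07,1.46,0.24
OSEM,max,experimental,10,3.93,1.11,0.06
OSEM,max,experimental,10,6.03,1.05,0.11
OSEM,max,experimental,10,7.97,0.93,0.06
OSEM,max,experimental,8,2.07,1.11,0.08
OSEM,max,experimental,8,3.93,0.83,0.15
OSEM,max,experimental,8,6.03,0.83,0.03
OSEM,max,experimental,8,7.97,0.87,0.06
OSEM,max,experimental,6,2.07,0.7,0.04
OSEM,max,experimental,6,3.93,0.79,0.13
OSEM,max,experimental,6,6.03,0.7,0.13
OSEM,max,experimental,6,7.97,0.63,0.03
OSEM,max,experimental,5,2.07,0.67,0.23
OSEM,max,experimental,5,3.93,0.48,0.08
OSEM,max,experimental,5,6.03,0.47,0.05
OSEM,max,experimental,5,7.97,0.42,0.1
OSEM,max,experimental,4,2.07,0.55,0.14
OSEM,max,experimental,4,3.93,0.38,0.07
OSEM,max,experimental,4,6.03,0.41,0.11
OSEM,max,experimental,4,7.97,0.3,0.08
OSEM,max,simulated,13,2.07,1.49,0.08
OSEM,max,simulated,13,3.93,1.26,0.04
OSEM,max,simulated,13,6.03,1.16,0.04
OSEM,max,simulated,13,7.97,1.11,0.03
OSEM,max,simulated,10,2.07,1.49,0.17
OSEM,max,simulated,10,3.93,1.27,0.13
OSEM,max,simulated,10,6.03,1.16,0.11
OSEM,max,simulated,10,7.97,1.1,0.09
OSEM,max,simulated,8,2.07,1.08,0.23
OSEM,max,simulated,8,3.93,0.92,0.03
OSEM,max,simulated,8,6.03,0.84,0.04
OSEM,max,simulated,8,7.97,0.75,0.1
OSEM,max,simulated,6,2.07,0.98,0.07
OSEM,max,simulated,6,3.93,0.81,0.03
OSEM,max,simulated,6,6.03,0.74,0.04
OSEM,max,simulated,6,7.97,0.65,0.11
OSEM,max,simulated,5,2.07,0.72,0.06
OSEM,max,simulated,5,3.93,0.55,0.05
OSEM,max,simulated,5,6.03,0.49,0.06
OSEM,max,simulated,5,7.97,0.44,0.09
OSEM,max,simulated,4,2.07,0.62,0.16
OSEM,max,simulated,4,3.93,0.42,0.08
OSEM,max,simulated,4,6.03,0.34,0.07
OSEM,max,simulated,4,7.97,0.31,0.05
BPL,mean,experimental,13,2.07,0.7,0.04
BPL,mean,experimental,13,3.93,0.73,0.01
BPL,mean,experimental,13,6.03,0.73,0.01
BPL,mean,experimental,13,7.97,0.7,0.01
BPL,mean,experimental,10,2.07,0.69,0.03
BPL,mean,experimental,10,3.93,0.69,0.01
BPL,mean,experimental,10,6.03,0.71,0.01
BPL,mean,experimental,10,7.97,0.7,0.01
BPL,mean,experimental,8,2.07,0.59,0.05
BPL,mean,experimental,8,3.93,0.54,0.05
BPL,mean,experimental,8,6.03,0.61,0.02
BPL,mean,experimental,8,7.97,0.59,0.0
BPL,mean,experimental,6,2.07,0.44,0.06
BPL,mean,experimental,6,3.93,0.49,0.02
BPL,mean,experimental,6,6.03,0.51,0.03
BPL,mean,experimental,6,7.97,0.47,0.08
BPL,mean,experimental,5,2.07,0.41,0.09
BPL,mean,experimental,5,3.93,0.34,0.05
BPL,mean,experimental,5,6.03,0.33,0.04
BPL,mean,experimental,5,7.97,0.35,0.06
BPL,mean,experimental,4,2.07,0.4,0.07
BPL,mean,experimental,4,3.93,0.27,0.03
BPL,mean,experimental,4,6.03,0.31,0.04
BPL,mean,experimental,4,7.97,0.28,0.05
BPL,mean,simulated,13,2.07,0.75,0.04
BPL,mean,simulated,13,3.93,0.73,0.02
BPL,mean,simulated,13,6.03,0.74,0.01
BPL,mean,simulated,13,7.97,0.74,0.01
BPL,mean,simulated,10,2.07,0.73,0.05
BPL,mean,simulated,10,3.93,0.72,0.02
BPL,mean,simulated,10,6.03,0.74,0.02
BPL,mean,simulated,10,7.97,0.73,0.01
BPL,mean,simulated,8,2.07,0.59,0.03
BPL,mean,simulated,8,3.93,0.61,0.02
BPL,mean,simulated,8,6.03,0.65,0.03
BPL,mean,simulated,8,7.97,0.65,0.01
BPL,mean,simulated,6,2.07,0.44,0.03
BPL,mean,simulated,6,3.93,0.46,0.03
BPL,mean,simulated,6,6.03,0.51,0.06
BPL,mean,simulated,6,7.97,0.52,0.02
BPL,mean,simulated,5,2.07,0.35,0.07
BPL,mean,simulated,5,3.93,0.28,0.05
BPL,mean,simulated,5,6.03,0.29,0.03
BPL,mean,simulated,5,7.97,0.3,0.04
BPL,mean,simulated,4,2.07,0.4,0.07
BPL,mean,simulated,4,3.93,0.3,0.05
BPL,mean,simulated,4,6.03,0.27,0.05
BPL,mean,simulated,4,7.97,0.25,0.04
BPL,max,experimental,13,2.07,1.65,0.3
BPL,max,experimental,13,3.93,1.65,0.38
BPL,max,experimental,13,6.03,1.37,0.03
BPL,max,experimental,13,7.97,1.39,0.12
BPL,max,experimental,10,2.07,1.57,0.31
BPL,max,experimental,10,3.93,1.62,0.2
BPL,max,experimental,10,6.03,1.46,0.05
BPL,max,experimental,10,7.97,1.4,0.09
BPL,max,experimental,8,2.07,1.06,0.23
BPL,max,experimental,8,3.93,1.06,0.3
BPL,max,experimental,8,6.03,1.28,0.1
BPL,max,experimental,8,7.97,1.55,0.42
BPL,max,experimental,6,2.07,0.64,0.12
BPL,max,experimental,6,3.93,0.85,0.06
BPL,max,experimental,6,6.03,1.06,0.28
BPL,max,experimental,6,7.97,1.02,0.18
BPL,max,experimental,5,2.07,0.54,0.15
BPL,max,experimental,5,3.93,0.5,0.01
BPL,max,experimental,5,6.03,0.45,0.08
BPL,max,experimental,5,7.97,0.51,0.06
BPL,max,experimental,4,2.07,0.49,0.06
BPL,max,experimental,4,3.93,0.4,0.04
BPL,max,experimental,4,6.03,0.4,0.07
BPL,max,experimental,4,7.97,0.36,0.08
BPL,max,simulated,13,2.07,1.78,0.13
BPL,max,simulated,13,3.93,1.62,0.06
BPL,max,simulated,13,6.03,1.51,0.05
BPL,max,simulated,13,7.97,1.43,0.07
BPL,max,simulated,10,2.07,1.63,0.21
BPL,max,simulated,10,3.93,1.77,0.18
BPL,max,simulated,10,6.03,1.78,0.19
BPL,max,simulated,10,7.97,1.59,0.13
BPL,max,simulated,8,2.07,1.05,0.17
BPL,max,simulated,8,3.93,1.18,0.27
BPL,max,simulated,8,6.03,1.46,0.18
BPL,max,simulated,8,7.97,1.47,0.06
BPL,max,simulated,6,2.07,0.75,0.04
BPL,max,simulated,6,3.93,0.8,0.06
BPL,max,simulated,6,6.03,1.03,0.08
BPL,max,simulated,6,7.97,1.11,0.11
BPL,max,simulated,5,2.07,0.49,0.09
BPL,max,simulated,5,3.93,0.4,0.05
BPL,max,simulated,5,6.03,0.42,0.01
BPL,max,simulated,5,7.97,0.46,0.02
BPL,max,simulated,4,2.07,0.47,0.12
BPL,max,simulated,4,3.93,0.37,0.06
BPL,max,simulated,4,6.03,0.33,0.07
BPL,max,simulated,4,7.97,0.31,0.05
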