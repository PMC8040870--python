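cultivar,temperature_c,rh_pct,duration_d,mfv_grain_weight,mfv_head_rice_rate,mfv_chalkiness,mean_mfv
LY27,33,75,8,0.37,0.89,0.82,0.70
LY27,33,75,15,0.26,0.79,0.63,0.56
LY27,33,85,8,1.00,0.88,0.74,0.87
LY27,33,85,15,0.66,0.87,0.73,0.75
LY27,35,75,8,0.12,0.68,0.60,0.47
LY27,35,75,15,0.29,0.49,0.49,0.42
LY27,35,85,8,0.80,0.74,0.71,0.75
LY27,35,85,15,0.29,0.74,0.75,0.59
LY27,37,75,8,0.16,0.50,0.41,0.35
LY27,37,75,15,0.07,0.49,0.40,0.32
LY27,37,85,8,0.23,0.54,0.49,0.42
LY27,37,85,15,0.19,0.36,0.32,0.29
LY6,33,75,8,0.57,0.73,0.63,0.64
LY6,33,75,15,0.28,0.71,0.49,0.49
LY6,33,85,8,0.68,0.86,0.74,0.76
LY6,33,85,15,0.50,0.82,0.71,0.68
LY6,35,75,8,0.35,0.48,0.48,0.44
LY6,35,75,15,0.27,0.45,0.42,0.38
LY6,35,85,8,0.55,0.69,0.66,0.64
LY6,35,85,15,0.40,0.66,0.68,0.58
LY6,37,75,8,0.40,0.22,0.37,0.33
LY6,37,75,15,0.28,0.07,0.27,0.21
LY6,37,85,8,0.52,0.33,0.43,0.43
LY6,37,85,15,0.35,0.34,0.42,0.37
ZLY47,33,75,8,0.63,0.66,0.49,0.60
ZLY47,33,75,15,0.49,0.63,0.38,0.50
ZLY47,33,85,8,0.63,0.81,0.59,0.68
ZLY47,33,85,15,0.81,0.84,0.57,0.74
ZLY47,35,75,8,0.33,0.32,0.52,0.39
ZLY47,35,75,15,0.31,0.25,0.38,0.31
ZLY47,35,85,8,0.37,0.65,0.53,0.52
ZLY47,35,85,15,0.40,0.53,0.47,0.47
ZLY47,37,75,8,0.25,0.31,0.50,0.35
ZLY47,37,75,15,0.08,0.22,0.40,0.24
ZLY47,37,85,8,0.39,0.29,0.38,0.35
ZLY47,37,85,15,0.25,0.23,0.38,0.28
R168,33,75,8,0.50,0.96,0.98,0.81
R168,33,75,15,0.41,0.88,0.89,0.73
R168,33,85,8,0.43,0.92,0.95,0.77
R168,33,85,15,0.51,0.85,0.92,0.76
R168,35,75,8,0.47,0.82,0.89,0.73
R168,35,75,15,0.38,0.80,0.93,0.70
R168,35,85,8,0.63,0.96,0.96,0.85
R168,35,85,15,0.41,0.85,0.92,0.73
R168,37,75,8,0.55,0.67,0.68,0.63
R168,37,75,15,0.18,0.53,0.71,0.47
R168,37,85,8,0.44,0.73,0.75,0.64
R168,37,85,15,0.32,0.70,0.78,0.60
IR64,33,75,8,0.55,0.80,0.96,0.77
IR64,33,75,15,0.66,0.71,0.94,0.77
IR64,33,85,8,0.76,0.83,1.00,0.86
IR64,33,85,15,0.71,0.86,0.96,0.84
IR64,35,75,8,0.37,0.27,0.74,0.46
IR64,35,75,15,0.46,0.29,0.55,0.43
IR64,35,85,8,0.63,0.43,0.80,0.62
IR64,35,85,15,0.47,0.27,0.73,0.49
IR64,37,75,8,0.38,0.17,0.61,0.39
IR64,37,75,15,0.29,0.00,0.52,0.27
IR64,37,85,8,0.47,0.15,0.67,0.43
IR64,37,85,15,0.39,0.10,0.39,0.29
16343,33,75,8,0.72,0.97,0.76,0.82
16343,33,75,15,0.51,1.00,0.61,0.71
16343,33,85,8,0.82,0.85,0.78,0.82
16343,33,85,15,0.68,0.98,0.77,0.81
16343,35,75,8,0.19,0.25,0.39,0.28
16343,35,75,15,0.09,0.26,0.21,0.19
16343,35,85,8,0.44,0.43,0.65,0.51
16343,35,85,15,0.43,0.33,0.32,0.36
16343,37,75,8,0.06,0.28,0.11,0.15
16343,37,75,15,0.00,0.19,0.05,0.08
16343,37,85,8,0.29,0.36,0.53,0.39
16343,37,85,15,0.26,0.27,0.00,0.18
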