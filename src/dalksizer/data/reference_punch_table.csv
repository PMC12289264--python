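K_D,6.00,6.25,6.50,6.75,7.00,7.25,7.50,7.75,8.00
45,6.17,6.45,6.72,7.00,7.28,7.57,7.85,8.14,8.44
46,6.18,6.46,6.73,7.01,7.30,7.58,7.87,8.16,8.46
47,6.19,6.47,6.75,7.03,7.31,7.6,7.89,8.19,8.49
48,6.20,6.48,6.76,7.04,7.33,7.62,7.91,8.21,8.51
49,6.21,6.49,6.77,7.05,7.34,7.63,7.93,8.23,8.54
50,6.22,6.50,6.78,7.07,7.36,7.65,7.95,8.25,8.56
51,6.23,6.51,6.79,7.08,7.38,7.67,7.97,8.28,8.59
52,6.24,6.52,6.81,7.10,7.39,7.69,8.00,8.31,8.62
53,6.25,6.53,6.82,7.11,7.41,7.71,8.02,8.33,8.65
54,6.26,6.54,6.84,7.13,7.43,7.73,8.04,8.36,8.68
55,6.27,6.56,6.85,7.15,7.45,7.76,8.07,8.39,8.71
56,6.28,6.57,6.87,7.16,7.47,7.78,8.09,8.42,8.75
57,6.29,6.58,6.88,7.18,7.49,7.8,8.12,8.45,8.78
58,6.30,6.60,6.90,7.20,7.51,7.83,8.15,8.48,8.82
59,6.32,6.61,6.91,7.22,7.53,7.85,8.18,8.51,8.86
60,6.33,6.63,6.93,7.24,7.56,7.88,8.21,8.55,8.90
61,6.34,6.64,6.95,7.26,7.58,7.91,8.24,8.59,8.94
62,6.35,6.66,6.97,7.28,7.60,7.93,8.27,8.62,8.99
63,6.37,6.67,6.98,7.30,7.63,7.96,8.31,8.66,9.03
64,6.38,6.69,7.00,7.32,7.65,7.99,8.34,8.71,9.08
65,6.40,6.71,7.02,7.35,7.68,8.03,8.38,8.75,9.13
66,6.41,6.72,7.04,7.37,7.71,8.06,8.42,8.79,9.19
67,6.43,6.74,7.06,7.40,7.74,8.09,8.46,8.84,9.24
68,6.44,6.76,7.09,7.42,7.77,8.13,8.50,8.89,9.30
69,6.46,6.78,7.11,7.45,7.80,8.17,8.55,8.95,9.37
70,6.48,6.80,7.13,7.48,7.83,8.20,8.59,9.00,9.43
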