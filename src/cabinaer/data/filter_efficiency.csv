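status,ionization,bound,eta_10,eta_14,eta_19,eta_27,eta_37,eta_52,eta_72,eta_100,eta_139,eta_193,eta_253,eta_298,eta_352,eta_414,eta_488,eta_576,eta_679,eta_800,eta_943,eta_1112,eta_1310,eta_1545,eta_1821,eta_2146,eta_2530
new,off,upper,0.79,0.79,0.79,0.79,0.79,0.79,0.78,0.76,0.76,0.71,0.68,0.68,0.68,0.98,0.99,0.99,0.99,0.99,0.99,0.99,0.99,0.99,0.99,0.99,0.99
aged_500h,off,upper,0.56,0.56,0.56,0.56,0.56,0.56,0.49,0.42,0.42,0.33,0.33,0.29,0.29,0.66,0.67,0.67,0.67,0.67,0.67,0.67,0.67,0.67,0.67,0.67,0.67
new,on,upper,0.88,0.88,0.88,0.88,0.88,0.88,0.88,0.88,0.90,0.91,0.92,0.92,0.93,0.99,0.99,0.99,0.99,0.99,0.99,0.99,0.99,0.99,0.99,0.99,0.99
aged_500h,on,upper,0.65,0.65,0.65,0.65,0.65,0.65,0.58,0.51,0.51,0.42,0.42,0.38,0.38,0.75,0.76,0.76,0.76,0.76,0.76,0.76,0.76,0.76,0.76,0.76,0.76
new,off,lower,0.65,0.65,0.65,0.65,0.65,0.65,0.65,0.65,0.64,0.64,0.61,0.63,0.69,0.77,0.77,0.77,0.82,0.84,0.84,0.89,0.89,0.92,0.92,0.95,0.95
aged_500h,off,lower,0.25,0.25,0.25,0.25,0.25,0.25,0.25,0.25,0.25,0.25,0.25,0.25,0.25,0.37,0.37,0.37,0.42,0.44,0.44,0.49,0.49,0.52,0.52,0.55,0.55
new,on,lower,0.87,0.87,0.87,0.87,0.87,0.87,0.87,0.87,0.87,0.87,0.87,0.87,0.87,0.87,0.94,0.94,0.95,0.96,0.96,0.94,0.94,0.98,0.98,0.95,0.95
aged_500h,on,lower,0.34,0.34,0.34,0.34,0.34,0.34,0.34,0.34,0.34,0.34,0.34,0.34,0.34,0.46,0.46,0.46,0.51,0.53,0.53,0.58,0.58,0.61,0.61,0.64,0.64
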