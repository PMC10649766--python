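# Marginals of the 112-patient verification cohort (raw units).
[cohort]
n = 112
residual_sd = 0.084
kvp_steps = 70 80 100 120 140

[age]
mean = 55.0
sd = 13.9
min = 31
max = 88

[kvp]
mean = 118.4
sd = 5.5
min = 100
max = 120

[bsa]
mean = 1.81
sd = 0.19
min = 1.25
max = 2.39

[hr]
mean = 72.3
sd = 12.2
min = 45
max = 103

[co]
mean = 6.45
sd = 0.77
min = 4.5
max = 9.6

[cm]
mean = 54.4
sd = 8.9
min = 32
max = 68

[dtt]
mean = 3.86
sd = 0.32
min = 2.37
max = 4.61
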