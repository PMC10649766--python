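# Marginals of the 450-patient derivation cohort (raw units).
[cohort]
n = 450
residual_sd = 0.084
kvp_steps = 70 80 100 120 140

[age]
mean = 56
sd = 13.3
min = 24
max = 90

[kvp]
mean = 100
sd = 19.0
min = 70
max = 140

[bsa]
mean = 1.75
sd = 0.20
min = 1.27
max = 2.70

[hr]
mean = 72.1
sd = 12.8
min = 45
max = 139

[co]
mean = 6.32
sd = 1.06
min = 4.18
max = 11.11

[cm]
mean = 36.7
sd = 11.5
min = 17
max = 75

[dtt]
mean = 3.08
sd = 0.53
min = 2.00
max = 5.13
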