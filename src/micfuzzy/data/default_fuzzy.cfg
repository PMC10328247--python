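input.Low = 0 0 0.5
input.Medium = 0 0.5 1
input.High = 0.5 1 1
output.VL = 0 0 0.25
output.L = 0 0.25 0.5
output.Med = 0.25 0.5 0.75
output.H = 0.5 0.75 1
output.VH = 0.75 1 1
rule.Low.Low = Med
rule.Low.Medium = L
rule.Low.High = VL
rule.Medium.Low = H
rule.Medium.Medium = Med
rule.Medium.High = L
rule.High.Low = VH
rule.High.Medium = H
rule.High.High = Med
defuzz_resolution = 0.001
firing_epsilon = 1e-09
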