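# Loop-strength sweep of the four-node genetic DNF circuit
# (shipped default parameter set; AHL strength folded into fs).
family = "genetic"
topology = "DNF"
beta = 0.1
n = 1.5
alpha = 10.0
theta = 5.0
q = 2.0
lam = 1.0
atc = 0.0
mode = "subtractive"
floor = 1e-3
fs_min = 0.0
fs_max = 5.0
fs_points = 51
x_min = 1e-4
x_max = 1e5
x_points = 61
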