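
# Two-population worked example: a randomly sampled dissipative network
# used throughout the documentation and tests.
sigma:
- [1.45, 1.77]
- [0.45, 1.98]
d: [1.20, 1.80]
N0: [1.00, 1.20]
metadata:
  label: two-population worked example
  # dissipative: symmetric part has minimum eigenvalue ~0.574
  # maintenance supply d.N0 = 3.36 (the critical supply Q_c)
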