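"""How sensitive are field statistics to the initial tip count N0?

Sweeps N0 at the wild-type Tm20 rates.  Below ~20 initial tips the
quantile estimate underlying R95 is noisy and biased; above 20 the mean
changes little, which is why N0 = 30 is the standard choice.
"""

from dendrosim import n0_sensitivity

table = n0_sensitivity([5, 10, 20, 30, 50], n_neurons=100, master_seed=9)
print(table.round(3).to_string(index=False))
print()
print("mean_r95 flattens out above N0 ~ 20; the residual drift reflects the")
print("95th-percentile estimator seeing more terminal points per neuron.")
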