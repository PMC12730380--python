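"""Significance of a directed GC value by circular-shift surrogates.

Rotating the source channel by a random offset destroys its temporal
relation to the target while leaving both spectra untouched, giving a null
distribution of I^1 under "no directed interaction". The coupled pair is
far outside its null; the uncoupled pair is not.
"""

import numpy as np

import specgc as sg

for label, c in (("coupled (c=0.4)", 0.4), ("uncoupled (c=0)", 0.0)):
    model = sg.make_unidirectional_var(a=0.5, c=c, d=0.7)
    seg = sg.simulate_var(model, n_samples=500, n_trials=8, seed=3, fs=1000.0)
    null = sg.surrogate_null(
        seg, pair=("Y", "X"), method="circular_shift",
        n_surrogates=199, seed=4, n_freq=128,
    )
    q95 = float(np.quantile(null.samples[:, 0], 0.95))
    print(f"{label:>16}: observed I^1 = {null.observed[0]:.4f}, "
          f"null 95th percentile = {q95:.4f}, p = {null.p_value(1):.4f}")

print("\np is the empirical tail probability (1 + #exceedances)/(1 + n_surrogates);"
      "\nvalues below 0.05 reject the no-interaction null for Y->X.")
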