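"""Trial-to-trial variability and efficiency of a population code.

The same 1.5 s filtered-noise stimulus is presented repeatedly, each trial
preceded by a different random 500 ms start-stimulus. With no noise anywhere
else, any across-trial spike variability reflects degeneracy of the code:
many spike patterns reconstruct the stimulus equally well. The coincidence
factor Gamma-bar (1 = identical trains, ~0 = chance) quantifies it.
"""

import predcoding as pc

stim = pc.make_stimulus("filtered_noise", 1500.0, 0.1, amplitude=5.0, tau=15.0, seed=8)

for kind in ("homogeneous", "heterogeneous"):
    bank = pc.build_filter_bank(kind, 100, nu=1.5, mu=1.5, seed=2)
    trials = pc.run_trials(bank, stim, n_trials=4, start_stimulus_duration=500.0, seeds=9)
    rep = pc.evaluate_trials(trials)
    print(
        f"{kind:14s} Gammā = {rep.gamma_mean:5.2f}   MSE̅ = {rep.mse_norm:5.3f}   "
        f"A = {rep.activity:5.1f} Hz   E = {rep.efficiency:5.2f} s"
    )

# Low Gamma-bar with low MSE is the signature of a degenerate but accurate
# code; the heterogeneous network reaches a lower error (higher efficiency)
# for moderate-amplitude, fast-fluctuating stimuli.
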