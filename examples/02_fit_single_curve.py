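"""Invert a noisy curve for the blood flow index.

Simulates one noisy g2 curve with known BFI and coherence factor, fits it
with the Nelder-Mead inversion, and prints truth vs estimate. The relative
errors show the single-curve precision at the default noise level.
"""

from dcsflow import NoiseModel, OpticalProperties, fit_curve, simulate_curve

optics = OpticalProperties()
true_bfi, rho_cm = 2e-8, 0.5
noise = NoiseModel(sigma0=0.005, profile="constant")

curve = simulate_curve(true_bfi, optics, rho_cm, noise, seed=4)
est = fit_curve(curve, optics)

print(f"true BFI   = {true_bfi:.4e} cm^2/s   true beta = {noise.beta}")
print(f"fitted BFI = {est.bfi:.4e} cm^2/s   fitted beta = {est.beta:.4f}")
print(f"relative BFI error = {100 * (est.bfi - true_bfi) / true_bfi:+.2f} %")
print(f"converged = {est.converged}, sse = {est.sse:.3e}, lags used = {est.n_lags_used}")
print()
print("With sigma = 0.005 additive g2 noise the single-curve BFI error is a few")
print("percent; averaging 30 repeats per site reduces it well below the")
print("week-to-week physiological variability.")
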