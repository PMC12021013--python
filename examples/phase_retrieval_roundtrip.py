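"""Reconstruct a known phase object from a synthetic defocus pair.

Builds a smooth Gaussian phase bump, renders it into over/under focused
brightfield images with the discrete TIE forward model, and inverts them with
the spectral solver at zero damping.
"""

import numpy as np

from tiettd import OpticalConfig, forward_tie_pair, gaussian_phase, solve_tie

config = OpticalConfig(
    wavelength=0.486,        # um, blue illumination
    n_imm=1.0,               # dry objective
    defocus_separation=1.0,  # planes at +/-0.5 um
    pixel_size=0.3,          # um/px
)

phase = gaussian_phase(amplitude=1.0, sigma_um=6.0, pixel_size=0.3)
pair = forward_tie_pair(phase, base_intensity=1000.0, config=config)
T = solve_tie(pair, regularization=0.0)

expected = phase.values[1:-1, 1:-1]
expected = expected - expected.mean()
err = np.linalg.norm(T.values - expected) / np.linalg.norm(expected)

print(f"input pair shape : {pair.bf_over.shape}")
print(f"output T shape   : {T.values.shape}  (1-px border trimmed per side)")
print(f"relative L2 error: {err:.2e}")
print("The reconstruction equals the true phase minus its mean: with no")
print("damping the spectral inversion is the exact inverse of the forward")
print("model, so the error is at machine precision.")
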