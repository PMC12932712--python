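"""Single-shot phase retrieval of one bead projection with PWF.

Simulates one speckle projection of the default three-bead phantom,
retrieves the complex phase map with preconditioned Wirtinger flow using
the simulation's diffuser screen, and compares the retrieved phase with
the analytic ground truth inside the sample-transfer band.
"""
import numpy as np

from pwftomo import IntensityImage2D, SolverParams, solve
from pwftomo.coherence import stf_window
from pwftomo.simulate import (default_config, default_phantom,
                              make_diffuser_screen, simulate_dataset)
from pwftomo.solver import background_border_mask

cfg = default_config(seed=1, n=128, n_angles=1)
ds = simulate_dataset(default_phantom(), cfg)
geom = cfg.geometry
screen = make_diffuser_screen(cfg)

params = SolverParams(alpha=0.1 + 0.0j, max_iter=600, min_iter=600)
result = solve(IntensityImage2D(ds.projections[0], geom), screen,
               cfg.coherence, geom, params,
               reference_mean=float(ds.reference.mean()))

mask = background_border_mask(geom, params.background_fraction)
truth = ds.truth_psi[0].imag
truth = truth - truth[mask].mean()
stf = stf_window(cfg.coherence, geom, params.gamma)
band = lambda a: np.fft.ifft2(stf * np.fft.fft2(a)).real
err = np.sqrt(np.mean((band(result.psi.values.imag) - band(truth)) ** 2))

print(f"iterations           : {result.iterations}")
print(f"final loss           : {result.loss_history[-1]:.3e}")
print(f"peak |phase| truth   : {np.abs(truth).max():.2f} rad")
print(f"band-limited phase error: {err / np.ptp(band(truth)):.1%} of range")
print(f"mean residual (RMSE image): {result.rmse_image.mean():.3f} % of reference")
print("A few-percent band-limited phase error and a sub-percent, spatially")
print("uniform intensity residual indicate a quantitative single-shot fit.")
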