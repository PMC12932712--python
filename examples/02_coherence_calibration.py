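"""Siegert coherence calibration and the expected-resolution estimate.

Simulates a partially coherent reference speckle (coherent speckle blurred
by a Gaussian intensity PSF), calibrates the coherence lengths from its
autocorrelation via the Siegert relation, and evaluates the expected
spatial resolution at the STF = 0.1 bandwidth boundary — including the
values for the beamline-calibrated coherence lengths (3.47 / 4.31 um).
"""
import numpy as np

from pwftomo import CoherenceModel, ImagingGeometry, IntensityImage2D, iotf
from pwftomo.coherence import calibrate_coherence, expected_resolution

rng = np.random.default_rng(0)
geom = ImagingGeometry(nx=1024, ny=1024, pitch=650e-9, wavelength=0.124e-9)
true = CoherenceModel(x_coh=3.47e-6, y_coh=4.31e-6)

field = rng.standard_normal((1024, 1024)) + 1j * rng.standard_normal((1024, 1024))
coherent = np.abs(field) ** 2
blurred = np.fft.ifft2(iotf(true, geom) * np.fft.fft2(coherent)).real
cal = calibrate_coherence(IntensityImage2D(blurred, geom))

print(f"configured coherence lengths: {true.x_coh*1e6:.2f} / {true.y_coh*1e6:.2f} um")
print(f"calibrated coherence lengths: {cal.x_coh*1e6:.2f} / {cal.y_coh*1e6:.2f} um")
rx, ry, rms = expected_resolution(cal)
print(f"expected resolution (horizontal / vertical / rms): "
      f"{rx*1e6:.2f} / {ry*1e6:.2f} / {rms*1e6:.2f} um")
print("The Siegert fit recovers the blur widths to a few percent; the")
print("expected resolutions are ~0.385x the coherence lengths.")
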