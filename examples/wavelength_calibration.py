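"""Wavelength calibration of a spectrometer against neon emission lines.

A CCD spectrometer records detector pixel indices; mapping them to
wavelengths uses a low-order polynomial fit against the known emission
lines of a neon calibration lamp. Here a synthetic detector with 0.5 nm
per pixel starting at 400 nm is recovered exactly.
"""

import zeobench as zb

# strong visible neon lines (nm)
neon_lines = [585.249, 614.306, 640.225, 650.653, 703.241, 724.517]
# synthetic detector: pixel = (wavelength - 400) / 0.5
positions = [(nm - 400.0) / 0.5 for nm in neon_lines]

fit = zb.calibrate_wavelength(positions, neon_lines, degree=1)
intercept, slope = fit.coefficients
print(f"dispersion: {slope:.6f} nm/pixel, offset {intercept:.3f} nm")
print(f"largest residual: {fit.max_residual:.2e} nm")
print("check: pixel 500 ->", f"{fit.apply([500.0])[0]:.3f} nm")
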