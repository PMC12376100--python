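"""Raman lineshapes in the three canonical regimes of frequency modulation.

The lineshape is the Fourier transform of the phase-accumulating response
function damped by the 5 ps population lifetime.  A static frequency gives
the pure-lifetime Lorentzian; slow Ornstein-Uhlenbeck modulation gives the
inhomogeneous Gaussian; fast modulation is motionally narrowed.
"""

import numpy as np

from specmap import spectrum
from specmap.synthetic import make_frequency_traj
from specmap.units import C_CM_PER_PS, INVCM_TO_RAD_PER_PS

# static limit: Lorentzian with FWHM = 1 / (2 pi c T1)
const = make_frequency_traj("constant", n=4000, dt=0.1, mean=2130.0, t1=5.0)
s = spectrum(const, max_lag=60.0, zero_padding_factor=32)
print(f"static    : peak {s.peak:8.2f} cm^-1, FWHM {s.fwhm:6.3f} cm^-1 "
      f"(lifetime limit {1.0 / (2 * np.pi * C_CM_PER_PS * 5.0):.3f})")

# slow modulation (Delta tau_c >> 1): Gaussian, FWHM = 2 sqrt(2 ln 2) Delta
slow = make_frequency_traj("ou", n=40000, dt=0.1, delta=20.0, tau_c=5.0, t1=5.0, seed=2)
s = spectrum(slow, max_lag=3.0, zero_padding_factor=16)
print(f"slow OU   : peak {s.peak:8.2f} cm^-1, FWHM {s.fwhm:6.2f} cm^-1 "
      f"(Gaussian limit {2 * np.sqrt(2 * np.log(2)) * 20.0:.2f})")

# fast modulation (Delta tau_c << 1): motionally narrowed Lorentzian
delta_ang = 2.0  # rad/ps
fast = make_frequency_traj("ou", n=200000, dt=0.01,
                           delta=delta_ang / INVCM_TO_RAD_PER_PS, tau_c=0.02,
                           t1=5.0, seed=1)
s = spectrum(fast, max_lag=40.0, zero_padding_factor=8)
narrowed = (2 * delta_ang**2 * 0.02 + 0.2) / INVCM_TO_RAD_PER_PS
print(f"fast OU   : peak {s.peak:8.2f} cm^-1, FWHM {s.fwhm:6.2f} cm^-1 "
      f"(narrowed limit {narrowed:.2f})")
# Fast fluctuations of the same amplitude give a line an order of magnitude
# narrower than the slow-modulation Gaussian -- motional narrowing.
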