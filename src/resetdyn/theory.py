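"""Closed-form first-passage results for exactly solvable resetting models.

These reference curves serve as independent checks of the simulator and of
the trajectory-reweighting predictor, and as textbook baselines for users:

* free 1D diffusion (diffusivity D) from the origin to an absorbing target
  a distance L away, reset to the origin at rate r:
  <tau>_r = (e^(L sqrt(r/D)) - 1) / r, divergent as r -> 0;
* diffusion with constant drift v toward the target (inverse-Gaussian FPT),
  whose FPT Laplace transform f(r) = exp((x0 / 2D)(v - sqrt(v^2 + 4 D r)))
  gives <tau>_r = (1/f(r) - 1)/r with the finite r -> 0 limit x0 / v.

Both follow from the renewal identity <tau>_r = (1 - f(r)) / (r f(r)) for
Poissonian resetting to the starting point.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "free_diffusion_mfpt_under_reset",
    "drift_diffusion_fpt_laplace",
    "drift_diffusion_mfpt_under_reset",
]


def free_diffusion_mfpt_under_reset(distance, diffusivity, rate):
    """MFPT of reset free diffusion: (e^(L sqrt(r/D)) - 1) / r."""
    rate = np.asarray(rate, dtype=np.float64)
    return (np.exp(distance * np.sqrt(rate / diffusivity)) - 1.0) / rate


def drift_diffusion_fpt_laplace(x0, drift, diffusivity, rate):
    """Laplace transform at s = rate of the inverse-Gaussian FPT density."""
    rate = np.asarray(rate, dtype=np.float64)
    return np.exp(x0 / (2.0 * diffusivity) * (drift - np.sqrt(drift**2 + 4.0 * diffusivity * rate)))


def drift_diffusion_mfpt_under_reset(x0, drift, diffusivity, rate):
    """MFPT of reset drift-diffusion; equals x0/drift in the r -> 0 limit."""
    rate = np.asarray(rate, dtype=np.float64)
    f = drift_diffusion_fpt_laplace(x0, drift, diffusivity, rate)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (1.0 / f - 1.0) / rate
    return np.where(rate == 0, x0 / drift, out)
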