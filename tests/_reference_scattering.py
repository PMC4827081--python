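"""Independent scattering oracle: adaptive-RK transfer-matrix method.

Integrates the coupled-channel equation psi'' = 2 mu (V - E) psi with
DOP853 from the right edge to the left edge, one fundamental solution per
outgoing right channel, then solves for the combination with a unit
incoming wave in the entrance channel.  Entirely independent of the
package's Numerov boundary-value solver (different discretization,
different formulation), so agreement between the two validates both.

Valid for energies with both channels open on both sides (the only case
the transition-probability observable needs).
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp


def transfer_matrix_probabilities(model, e_total, *, rtol=1e-11,
                                  atol=1e-12):
    """(transmission, reflection) 2x2 matrices, diabatic channel order,
    [out, in], for left-incoming waves."""
    span = model.x_span
    two_mu = 2.0 * model.mass
    k_left = np.sqrt(two_mu * (e_total - np.asarray(model.asym_left)))
    k_right = np.sqrt(two_mu * (e_total - np.asarray(model.asym_right)))
    if np.any(~np.isfinite(k_left)) or np.any(~np.isfinite(k_right)):
        raise ValueError("all channels must be open for the oracle")

    def odes(x, y):
        psi = y[0:4].reshape(2, 2) + 1j * y[4:8].reshape(2, 2)
        dpsi = y[8:12].reshape(2, 2) + 1j * y[12:16].reshape(2, 2)
        ddpsi = two_mu * ((model.matrix(x) - e_total * np.eye(2)) @ psi)
        return np.concatenate([dpsi.real.ravel(), dpsi.imag.ravel(),
                               ddpsi.real.ravel(), ddpsi.imag.ravel()])

    # fundamental solutions: column c is a pure outgoing wave exp(i k_c x)
    # in channel c at the right edge (amplitude referenced to x = +span)
    psi0 = np.eye(2, dtype=complex)
    dpsi0 = np.diag(1j * k_right)
    y0 = np.concatenate([psi0.real.ravel(), psi0.imag.ravel(),
                         dpsi0.real.ravel(), dpsi0.imag.ravel()])
    sol = solve_ivp(odes, (span, -span), y0, method="DOP853",
                    rtol=rtol, atol=atol, dense_output=False)
    if not sol.success:
        raise RuntimeError(sol.message)
    yf = sol.y[:, -1]
    psi = yf[0:4].reshape(2, 2) + 1j * yf[4:8].reshape(2, 2)
    dpsi = yf[8:12].reshape(2, 2) + 1j * yf[12:16].reshape(2, 2)

    # left asymptote: psi_c = alpha_c e^{i k x'} + beta_c e^{-i k x'}
    # (x' referenced to the left edge); alpha is the incoming component
    alpha = 0.5 * (psi + dpsi / (1j * k_left[:, None]))
    beta = 0.5 * (psi - dpsi / (1j * k_left[:, None]))

    transmission = np.zeros((2, 2))
    reflection = np.zeros((2, 2))
    for ce in range(2):
        unit = np.zeros(2, dtype=complex)
        unit[ce] = 1.0
        coeff = np.linalg.solve(alpha, unit)   # t amplitudes per channel
        r_amp = beta @ coeff
        transmission[:, ce] = (k_right / k_left[ce]) * np.abs(coeff) ** 2
        reflection[:, ce] = (k_left / k_left[ce]) * np.abs(r_amp) ** 2
    return transmission, reflection
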