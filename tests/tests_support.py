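"""Small shared oracles for the test suite."""

import numpy as np


def finite_difference_jacobian(deform, coords, h=1e-4):
    """Central-difference Jacobian dPhi_i/dx_j of a deformation callable."""
    coords = np.asarray(coords, dtype=np.float64)
    J = np.zeros((coords.shape[0], 3, 3))
    for j in range(3):
        e = np.zeros(3)
        e[j] = h
        J[:, :, j] = (deform(coords + e) - deform(coords - e)) / (2 * h)
    return J
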