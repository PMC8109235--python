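"""Numba-compiled Parratt recursion kernel.

Layer convention used throughout: arrays of length ``n`` ordered from the
superphase (incident medium, index 0) to the subphase (index ``n - 1``).
``thickness[0]`` and ``thickness[-1]`` are ignored (semi-infinite media) and
``sigma2[i]`` is the *signed squared* Gaussian width attached to the
interface between layer ``i - 1`` and layer ``i`` (``sigma2[0]`` is
ignored): positive values give Nevot-Croce damping
``exp(-2 k k' sigma^2)``, small negative values undo the staircase bias of
midpoint micro-slicing.  SLDs are real, in units of 1e-6 per square
angstrom, so the normal wavevector in each layer is either purely real
(propagating) or purely imaginary (evanescent).
"""

import numpy as np
from numba import njit

_FOUR_PI = 4.0 * np.pi


@njit(cache=True, fastmath=True)
def parratt_kernel(q, thickness, rho, sigma2):
    """Specular reflectivity |r|^2 of a slab stack.

    With ``sigma2`` all zero this is the exact Abeles/Parratt result for
    sharp interfaces; positive entries apply Nevot-Croce roughness
    damping at the corresponding interface.
    """
    nq = q.shape[0]
    n = rho.shape[0]
    out = np.empty(nq)
    k = np.empty(n, dtype=np.complex128)
    for iq in range(nq):
        kz0sq = 0.25 * q[iq] * q[iq]
        for j in range(n):
            arg = kz0sq - _FOUR_PI * 1e-6 * (rho[j] - rho[0])
            if arg >= 0.0:
                k[j] = complex(np.sqrt(arg), 0.0)
            else:
                k[j] = complex(0.0, np.sqrt(-arg))
        r = 0.0 + 0.0j
        for j in range(n - 2, -1, -1):
            kj = k[j]
            kn = k[j + 1]
            rf = (kj - kn) / (kj + kn)
            if sigma2[j + 1] != 0.0:
                e = -2.0 * kj * kn * sigma2[j + 1]
                if e.imag == 0.0:
                    rf = rf * np.exp(e.real)
                else:
                    rf = rf * (np.exp(e.real)
                               * complex(np.cos(e.imag), np.sin(e.imag)))
            if j == n - 2:
                r = rf
            else:
                # phase factor exp(2 i k d): one sincos for propagating
                # layers, one real exp for evanescent ones
                if kn.imag == 0.0:
                    t = 2.0 * kn.real * thickness[j + 1]
                    ph = complex(np.cos(t), np.sin(t))
                else:
                    ph = complex(np.exp(-2.0 * kn.imag * thickness[j + 1]), 0.0)
                rp = r * ph
                r = (rf + rp) / (1.0 + rf * rp)
        out[iq] = min((r * np.conj(r)).real, 1.0)
    return out
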