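"""Independent numerical oracles used to validate closed forms.

Everything here is written from the defining relations only — no imports
from the package's model code beyond the parameter container — so that
agreement with the package is a genuine cross-check.
"""

import numpy as np
import scipy.constants as const
from scipy.optimize import brentq


def oracle_fermi_level(v_g: float, v_cnp: float, areal_capacitance: float,
                       fermi_velocity: float = 1.1e6, xtol: float = 1e-15) -> float:
    """Bisection solution of the bias balance for the Fermi level (eV).

    Solves  V_G − V_CNP = E_F/e + sign(E_F)·e·n(E_F)/c  with
    n = (|E_F|/(ħ v_F))²/π, by root bracketing on |E_F| ∈ [0, 10] eV.
    """
    dv = v_g - v_cnp
    if dv == 0.0:
        return 0.0
    sign = 1.0 if dv > 0 else -1.0

    def bias_mismatch(e_mag_ev: float) -> float:
        e_j = e_mag_ev * const.e
        n = (e_j / (const.hbar * fermi_velocity)) ** 2 / np.pi
        return e_mag_ev + const.e * n / areal_capacitance - abs(dv)

    mag = brentq(bias_mismatch, 0.0, 10.0, xtol=xtol)
    return sign * mag


def oracle_g_shift(e_f_ev: float, lambda_gamma: float = 0.03) -> float:
    """Linear G-band stiffening (cm⁻¹) from first principles constants."""
    cm_per_ev = const.e / (const.h * const.c) / 100.0
    return lambda_gamma / (2.0 * np.pi) * abs(e_f_ev) * cm_per_ev
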