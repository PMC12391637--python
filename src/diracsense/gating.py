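"""Electrostatic gating model of electrolyte-gated graphene.

The external bias :math:`V_G` applied between the functionalised gold
electrode and the graphene electrode drops partly across the electrical
double layers (lumped into a single series gate capacitance
:math:`C_{gate}`) and partly as a shift of the graphene Fermi level
:math:`E_F` away from the Dirac point:

.. math::

    V_G - V_{CNP} = \\operatorname{sign}(E_F)\\,\\frac{e\\,n}{c} + \\frac{E_F}{e},
    \\qquad
    n = \\frac{1}{\\pi}\\left(\\frac{|E_F|}{\\hbar v_F}\\right)^2,

where :math:`c = C_{gate}/A_g` is the areal gate capacitance and
:math:`V_{CNP}` the charge-neutrality-point voltage set by the initial
doping. Eliminating the carrier density :math:`n` gives a quadratic in
:math:`|E_F|`; its positive root, signed by :math:`V_G - V_{CNP}`, is the
closed form implemented here.

Via the electron–phonon coupling the Raman G band stiffens linearly with
the Fermi level magnitude,

.. math:: \\omega_G = \\omega_{G0} + \\frac{\\lambda_\\Gamma}{2\\pi}\\,|E_F|,

with :math:`|E_F|` converted to cm⁻¹; the linear law is quoted for
:math:`|E_F|` in the 100–500 meV window and evaluation outside it raises a
:class:`PhononValidityWarning` (but still returns the linear value, which
keeps optimisers usable near the CNP).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .constants import CONSTANTS, WAVENUMBER_PER_EV

__all__ = [
    "GatingParams",
    "PhononValidityWarning",
    "fermi_level",
    "bias_from_fermi",
    "carrier_density",
    "g_peak_shift",
    "predict_g_peak",
    "expected_molecules",
]

#: |E_F| window (eV) over which the linear G-band law is quoted.
PHONON_VALIDITY_WINDOW = (0.1, 0.5)


class PhononValidityWarning(UserWarning):
    """Fermi level outside the linear-dispersion validity window."""


@dataclass(frozen=True)
class GatingParams:
    """Device and material parameters of the gating model.

    Parameters
    ----------
    lambda_gamma : float
        Dimensionless electron–phonon coupling constant λ_Γ.
    fermi_velocity : float
        Fermi velocity v_F in m s⁻¹.
    omega_g0 : float
        G-peak wavenumber at the charge neutrality point, cm⁻¹.
    areal_capacitance : float
        Lumped gate capacitance per unit contact area, C_gate/A_g, F m⁻².
        This is the combination that actually enters the model and the
        quantity the dispersion fit estimates.
    contact_area : float
        Graphene/water contact area A_g in m², used only to report the
        total capacitance ``C_gate = areal_capacitance * contact_area``.
        The default is back-computed so a 5.26 × 10⁻² F m⁻² areal
        capacitance corresponds to a 1.72 µF total capacitance.
    v_cnp : float
        Charge-neutrality-point voltage in volts.
    """

    lambda_gamma: float = 0.03
    fermi_velocity: float = 1.1e6
    omega_g0: float = 1580.0
    areal_capacitance: float = 5.26e-2
    contact_area: float = 1.72e-6 / 5.26e-2
    v_cnp: float = 0.0

    def __post_init__(self) -> None:
        for name in ("lambda_gamma", "fermi_velocity", "areal_capacitance", "contact_area"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be finite and strictly positive, got {value!r}")
        if not np.isfinite(self.omega_g0):
            raise ValueError("omega_g0 must be finite")
        if not np.isfinite(self.v_cnp):
            raise ValueError("v_cnp must be finite")

    @property
    def total_capacitance(self) -> float:
        """Total gate capacitance C_gate in farads."""
        return self.areal_capacitance * self.contact_area

    @property
    def n_dop(self) -> float:
        """Initial carrier surface density (m⁻²) consistent with v_cnp.

        Defined through V_CNP = n_dop · e / (C_gate/A_g); carries the sign
        of v_cnp (positive for p-type initial doping under this sign
        convention).
        """
        return self.v_cnp * self.areal_capacitance / CONSTANTS.elementary_charge

    @classmethod
    def from_n_dop(cls, n_dop: float, **kwargs) -> "GatingParams":
        """Build params from an initial doping density instead of v_cnp."""
        base = cls(**kwargs)
        v_cnp = n_dop * CONSTANTS.elementary_charge / base.areal_capacitance
        return replace(base, v_cnp=v_cnp)

    def to_dict(self) -> dict:
        return {
            "lambda_gamma": self.lambda_gamma,
            "fermi_velocity": self.fermi_velocity,
            "omega_g0": self.omega_g0,
            "areal_capacitance": self.areal_capacitance,
            "contact_area": self.contact_area,
            "v_cnp": self.v_cnp,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GatingParams":
        return cls(**{k: float(v) for k, v in d.items()})


def _energy_scale(params: GatingParams) -> float:
    """π ħ² v_F² in J²·m² — the graphene DOS scale entering the quadratic."""
    hbar = CONSTANTS.reduced_planck
    return math.pi * hbar * hbar * params.fermi_velocity ** 2


def fermi_level(v_g, params: GatingParams):
    """Fermi level (eV, signed) of graphene at applied bias ``v_g`` (V).

    Closed form: with k = π ħ² v_F², c the areal capacitance, e the
    elementary charge and V = |v_g − v_cnp|,

        |E_F| = [ −kc/e² + sqrt((kc/e²)² + 4 k c V / e) ] / 2   (joules)

    i.e. the positive root of ``e E² / (k c) + E/e − V = 0`` obtained by
    eliminating the carrier density, then signed by (v_g − v_cnp).

    Accepts scalars or arrays; returns the matching shape.
    """
    v_g = np.asarray(v_g, dtype=float)
    if not np.all(np.isfinite(v_g)):
        raise ValueError("v_g must be finite")
    e = CONSTANTS.elementary_charge
    k = _energy_scale(params)
    c = params.areal_capacitance
    dv = v_g - params.v_cnp
    beta = k * c / (e * e)  # joules
    mag_j = 0.5 * (-beta + np.sqrt(beta * beta + 4.0 * k * c * np.abs(dv) / e))
    e_f = np.sign(dv) * mag_j / e  # eV
    return e_f if e_f.ndim else float(e_f)


def bias_from_fermi(e_f, params: GatingParams):
    """Inverse of :func:`fermi_level`: bias (V) that produces ``e_f`` (eV).

    Reconstructs V_G = v_cnp + E_F/e + sign(E_F)·e·n/c from the Fermi level
    and the carrier density it implies; used for round-trip validation.
    """
    e_f = np.asarray(e_f, dtype=float)
    if not np.all(np.isfinite(e_f)):
        raise ValueError("e_f must be finite")
    e = CONSTANTS.elementary_charge
    n = carrier_density(e_f, params)
    v = params.v_cnp + e_f + np.sign(e_f) * e * n / params.areal_capacitance
    return v if v.ndim else float(v)


def carrier_density(e_f, params: GatingParams | None = None):
    """Carrier surface density n (m⁻²) at Fermi level ``e_f`` (eV).

    n = (|E_F| / (ħ v_F))² / π with E_F in joules; even in E_F. Only the
    Fermi velocity enters; ``params`` defaults to the standard
    v_F = 1.1 × 10⁶ m s⁻¹.
    """
    if params is None:
        params = GatingParams()
    e_f = np.asarray(e_f, dtype=float)
    if not np.all(np.isfinite(e_f)):
        raise ValueError("e_f must be finite")
    e_j = np.abs(e_f) * CONSTANTS.elementary_charge
    n = (e_j / (CONSTANTS.reduced_planck * params.fermi_velocity)) ** 2 / math.pi
    return n if n.ndim else float(n)


def g_peak_shift(e_f, params: GatingParams | None = None, *, warn: bool = True):
    """G-band stiffening Δω_G (cm⁻¹) at Fermi level ``e_f`` (eV).

    Δω_G = (λ_Γ / 2π) · |E_F| with the energy expressed in cm⁻¹; even in
    E_F and nonnegative. Outside the 100–500 meV validity window a
    :class:`PhononValidityWarning` is emitted (suppress with
    ``warn=False``); the linear value is returned regardless.
    """
    if params is None:
        params = GatingParams()
    e_f = np.asarray(e_f, dtype=float)
    if not np.all(np.isfinite(e_f)):
        raise ValueError("e_f must be finite")
    mag = np.abs(e_f)
    if warn:
        lo, hi = PHONON_VALIDITY_WINDOW
        outside = (mag > 0) & ((mag < lo) | (mag > hi))
        if np.any(outside):
            warnings.warn(
                "linear G-band law evaluated outside the 100-500 meV validity window",
                PhononValidityWarning,
                stacklevel=2,
            )
    shift = (params.lambda_gamma / (2.0 * math.pi)) * mag * WAVENUMBER_PER_EV
    return shift if shift.ndim else float(shift)


def predict_g_peak(v_g, params: GatingParams, *, warn: bool = False):
    """G-peak position ω_G (cm⁻¹) at bias ``v_g`` (V).

    Composition ω_G = ω_G0 + Δω_G(E_F(V_G)); V-shaped in V_G with its
    global minimum ω_G0 exactly at v_cnp. Warnings off by default because
    the fit routinely evaluates the model through the near-CNP region.
    """
    return params.omega_g0 + g_peak_shift(fermi_level(v_g, params), params, warn=warn)


def expected_molecules(concentration: float, volume: float) -> tuple[float, float]:
    """Expected analyte molecule count in a solution droplet.

    Parameters
    ----------
    concentration : float
        Molar concentration (mol L⁻¹), ≥ 0.
    volume : float
        Solution volume in litres, > 0.

    Returns
    -------
    (count, sd) : tuple of float
        Expected count c·N_A·V and its Poisson standard deviation
        sqrt(count). Rounding to an integer is left to the caller.
    """
    if not np.isfinite(concentration) or concentration < 0:
        raise ValueError("concentration must be finite and nonnegative")
    if not np.isfinite(volume) or volume <= 0:
        raise ValueError("volume must be finite and positive")
    count = concentration * CONSTANTS.avogadro * volume
    return count, math.sqrt(count)
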