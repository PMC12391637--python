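"""Physical constants and unit conversions used throughout the package.

Energies are carried in eV internally; Raman shifts in cm⁻¹; capacitances in
SI (F, F m⁻²); potentials in volts unless a function explicitly says mV.
"""

from __future__ import annotations

from dataclasses import dataclass

import scipy.constants as _const

#: cm⁻¹ per eV (≈ 8065.54): E[cm⁻¹] = E[eV] · WAVENUMBER_PER_EV
WAVENUMBER_PER_EV: float = _const.e / (_const.h * _const.c) / 100.0

EV_PER_WAVENUMBER: float = 1.0 / WAVENUMBER_PER_EV


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants (SI) with the eV↔cm⁻¹ conversion pair.

    Attributes
    ----------
    elementary_charge : float
        e in coulombs.
    reduced_planck : float
        ħ in J·s.
    avogadro : float
        N_A in mol⁻¹.
    ev_per_wavenumber, wavenumber_per_ev : float
        Mutually inverse spectroscopic conversion factors.
    """

    elementary_charge: float = _const.e
    reduced_planck: float = _const.hbar
    avogadro: float = _const.N_A
    ev_per_wavenumber: float = EV_PER_WAVENUMBER
    wavenumber_per_ev: float = WAVENUMBER_PER_EV

    def __post_init__(self) -> None:
        for name in (
            "elementary_charge",
            "reduced_planck",
            "avogadro",
            "ev_per_wavenumber",
            "wavenumber_per_ev",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


CONSTANTS = PhysicalConstants()
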