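"""Charge-neutrality-point extraction from G-band dispersion curves.

The measured dispersion ω_G(V_G) is fitted by weighted nonlinear least
squares to the composed gating + electron–phonon model with exactly two
free parameters — the CNP voltage ``v_cnp`` and the areal gate capacitance
``C_gate/A_g`` — while λ_Γ, v_F and ω_G0 are held at their configured
constants. Exposed in the statsmodels idiom: build a
:class:`DispersionModel` from the data, call :meth:`DispersionModel.fit`,
and read estimates, standard errors and diagnostics off the returned
:class:`CNPFitResult` (or print :meth:`CNPFitResult.summary`).

Sweeps that stay entirely on one flank of the CNP — as in a 0 → −0.5 V
scan of a p-doped device — are accepted; the fitted CNP is then an
extrapolation beyond the scanned bias range and the result flags it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .constants import WAVENUMBER_PER_EV, CONSTANTS
from .gating import GatingParams, fermi_level, predict_g_peak, _energy_scale
from .spectra import DispersionCurve

__all__ = ["DispersionModel", "CNPFitResult", "initial_guess", "fit_dispersion"]

#: |E_F| (eV) below which, across a whole sweep, the capacitance is
#: effectively unidentifiable (the model is then linear in V_G alone).
_EF_IDENTIFIABILITY = 0.020


def _model_omega(bias: np.ndarray, v_cnp: float, areal_capacitance: float,
                 base: GatingParams) -> np.ndarray:
    p = replace(base, v_cnp=v_cnp, areal_capacitance=areal_capacitance)
    return predict_g_peak(bias, p)


def initial_guess(curve: DispersionCurve, base: GatingParams | None = None
                  ) -> tuple[float, float]:
    """Heuristic starting point (v_cnp0, areal_capacitance0) for the fit.

    If the ω minimum is interior to the sweep its bias is the CNP guess;
    for one-sided sweeps the guess is placed 0.3 V beyond the low-ω end of
    the scan, on the side the slope sign indicates. The capacitance guess
    matches the observed end-to-end slope |Δω/ΔV| to the large-|E_F| limit
    of the model, where ω grows like sqrt of the bias distance to the CNP.
    """
    if base is None:
        base = GatingParams()
    b, w = curve.bias, curve.omega
    imin = int(np.argmin(w))
    if 0 < imin < len(b) - 1:
        v0 = float(b[imin])
    elif imin == len(b) - 1:
        v0 = float(b[-1] + 0.3)   # ω still falling toward high bias: CNP above sweep
    else:
        v0 = float(b[0] - 0.3)    # CNP below the scanned range

    slope = abs((w[-1] - w[0]) / (b[-1] - b[0]))
    if slope <= 0:
        return v0, base.areal_capacitance
    # large-|E_F| limit: |E_F|(J) ≈ sqrt(k c V / e), so
    # dω/dV = (λ_Γ/2π)·conv · 0.5·sqrt(k c / (e V)) / e, solved for c at the
    # midpoint bias distance V_m from the guessed CNP.
    k = _energy_scale(base)
    e = CONSTANTS.elementary_charge
    pref = base.lambda_gamma / (2.0 * np.pi) * WAVENUMBER_PER_EV / e
    v_m = max(float(np.mean(np.abs(b - v0))), 1e-3)
    c0 = (2.0 * slope / pref) ** 2 * e * v_m / k
    c0 = float(np.clip(c0, 1e-4, 10.0))
    return v0, c0


class DispersionModel:
    """Two-parameter gating model for a measured ω_G(V_G) dispersion.

    Parameters
    ----------
    curve : DispersionCurve or (n, 3) table
        The (bias, ω_G, σ) data; weights are 1/σ².
    base : GatingParams, optional
        Carries the fixed constants λ_Γ, v_F, ω_G0 and the configured
        contact area used to report the total capacitance.
    """

    def __init__(self, curve, base: GatingParams | None = None):
        if not isinstance(curve, DispersionCurve):
            curve = DispersionCurve.from_table(curve)
        self.curve = curve
        self.base = base if base is not None else GatingParams()
        if np.ptp(curve.bias) < 0.1:
            warnings.warn("bias span < 0.1 V: the CNP fit may be ill-conditioned",
                          UserWarning, stacklevel=2)

    @classmethod
    def from_dataframe(cls, df, *, bias="bias", omega="omega", sigma="sigma",
                       base: GatingParams | None = None) -> "DispersionModel":
        """Build from a DataFrame with bias/omega/sigma columns."""
        curve = DispersionCurve(np.asarray(df[bias], dtype=float),
                                np.asarray(df[omega], dtype=float),
                                np.asarray(df[sigma], dtype=float))
        return cls(curve, base=base)

    # -- fitting -----------------------------------------------------------

    def predict(self, bias, params) -> np.ndarray:
        """Model ω_G at the given biases for params = (v_cnp, c_areal)."""
        return _model_omega(np.asarray(bias, dtype=float), params[0], params[1], self.base)

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        return (self.curve.omega - self.predict(self.curve.bias, x)) / self.curve.sigma

    def fit(self, start: tuple[float, float] | None = None,
            multistart: int = 5) -> "CNPFitResult":
        """Weighted least-squares fit; returns a :class:`CNPFitResult`.

        A trust-region reflective (Levenberg–Marquardt-like) optimiser is
        restarted from ``multistart`` CNP offsets around the heuristic
        guess and the lowest-cost solution kept. ``start`` overrides the
        heuristic entirely.
        """
        v0, c0 = initial_guess(self.curve, self.base) if start is None else start
        offsets = [0.0, 0.15, -0.15, 0.3, -0.3][:max(1, multistart)]
        best = None
        for dv in offsets:
            try:
                sol = least_squares(self._residuals, x0=[v0 + dv, c0],
                                    bounds=([-10.0, 1e-8], [10.0, 1e3]),
                                    x_scale=[0.1, max(c0, 1e-3)],
                                    xtol=1e-14, ftol=1e-14, gtol=1e-14)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError("dispersion fit failed from every start point")

        converged = bool(best.success)
        x = best.x
        n = len(self.curve)
        dof = max(n - 2, 1)
        chi2 = 2.0 * best.cost
        resid = self.curve.omega - self.predict(self.curve.bias, x)
        rmse = float(np.sqrt(np.mean(resid ** 2)))

        # Covariance of (v_cnp, c): residuals are already whitened by the
        # absolute σ, so cov = (JᵀJ)⁻¹ without rescaling by χ².
        J = best.jac
        try:
            cov = np.linalg.inv(J.T @ J)
        except np.linalg.LinAlgError:
            cov = np.full((2, 2), np.nan)
            converged = False
        bse = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))

        ef = fermi_level(self.curve.bias,
                         replace(self.base, v_cnp=x[0], areal_capacitance=x[1]))
        unident = bool(np.all(np.abs(ef) < _EF_IDENTIFIABILITY))
        extrap = not (self.curve.bias.min() <= x[0] <= self.curve.bias.max())

        return CNPFitResult(model=self, params=x, bse=bse, cov_params=cov,
                            reduced_chi2=chi2 / dof, rmse=rmse, n_points=n,
                            converged=converged, extrapolated=extrap,
                            capacitance_unidentifiable=unident)


@dataclass
class CNPFitResult:
    """Estimates, uncertainties and diagnostics of a dispersion fit.

    ``params`` is (v_cnp [V], areal_capacitance [F m⁻²]); ``bse`` the
    matching standard errors from the parameter covariance.
    """

    model: DispersionModel | None
    params: np.ndarray
    bse: np.ndarray
    cov_params: np.ndarray
    reduced_chi2: float
    rmse: float
    n_points: int
    converged: bool
    extrapolated: bool = False
    capacitance_unidentifiable: bool = False

    # -- named accessors (volts / farads) ----------------------------------

    @property
    def v_cnp(self) -> float:
        return float(self.params[0])

    @property
    def v_cnp_sd(self) -> float:
        return float(self.bse[0])

    @property
    def areal_capacitance(self) -> float:
        return float(self.params[1])

    @property
    def areal_capacitance_sd(self) -> float:
        return float(self.bse[1])

    @property
    def contact_area(self) -> float:
        base = self.model.base if self.model is not None else GatingParams()
        return base.contact_area

    @property
    def total_capacitance(self) -> float:
        """C_gate in farads, via the configured contact area."""
        return self.areal_capacitance * self.contact_area

    @property
    def total_capacitance_sd(self) -> float:
        return self.areal_capacitance_sd * self.contact_area

    @classmethod
    def from_values(cls, v_cnp: float, v_cnp_sd: float, *, converged: bool = True
                    ) -> "CNPFitResult":
        """Wrap an externally obtained (CNP, sd) pair, e.g. a literature
        table entry, so assay arithmetic can consume it."""
        nan2 = np.full((2, 2), np.nan)
        return cls(model=None, params=np.array([v_cnp, np.nan]),
                   bse=np.array([v_cnp_sd, np.nan]), cov_params=nan2,
                   reduced_chi2=np.nan, rmse=np.nan, n_points=0,
                   converged=converged, extrapolated=False)

    def predict(self, bias) -> np.ndarray:
        if self.model is None:
            raise ValueError("value-only result has no model to predict with")
        return self.model.predict(bias, self.params)

    def summary(self) -> str:
        """Human-readable fit report."""
        lines = [
            "G-band dispersion fit (weighted least squares)",
            "-" * 54,
            f"n points            : {self.n_points}",
            f"converged           : {self.converged}",
            f"CNP voltage         : {self.v_cnp * 1e3:10.1f} ± {self.v_cnp_sd * 1e3:.1f} mV"
            + ("   [extrapolated]" if self.extrapolated else ""),
            f"areal capacitance   : {self.areal_capacitance * 1e2:10.3f} ± "
            f"{self.areal_capacitance_sd * 1e2:.3f} µF cm⁻²",
            f"total capacitance   : {self.total_capacitance * 1e6:10.3f} ± "
            f"{self.total_capacitance_sd * 1e6:.3f} µF  (A_g = {self.contact_area:.3g} m²)",
            f"reduced chi²        : {self.reduced_chi2:10.3f}",
            f"rmse                : {self.rmse:10.4f} cm⁻¹",
        ]
        if self.capacitance_unidentifiable:
            lines.append("warning             : |E_F| < 20 meV over the whole sweep; "
                         "capacitance poorly identified")
        return "\n".join(lines)

    def plot(self, ax=None, n_grid: int = 200):
        """Data with error bars plus the fitted model curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.model.curve
        ax.errorbar(c.bias, c.omega, yerr=c.sigma, fmt="o", capsize=3, label="data")
        grid = np.linspace(c.bias.min(), c.bias.max(), n_grid)
        ax.plot(grid, self.predict(grid), "--", label="fit")
        ax.axvline(self.v_cnp, color="gray", lw=0.8)
        ax.set_xlabel("$V_G$ (V)")
        ax.set_ylabel(r"$\omega_G$ (cm$^{-1}$)")
        ax.legend()
        return ax


def fit_dispersion(curve, base: GatingParams | None = None,
                   start: tuple[float, float] | None = None) -> CNPFitResult:
    """Functional wrapper: ``DispersionModel(curve, base).fit(start)``."""
    return DispersionModel(curve, base=base).fit(start=start)
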