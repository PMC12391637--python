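"""Raman spectrum I/O, background subtraction and Lorentzian peak fitting.

Spectra are two-column plain text (wavenumber cm⁻¹, intensity counts;
``#`` comments; whitespace or comma separated). The G band lives in the
1550–1680 cm⁻¹ window and the 2D band in 2600–2830 cm⁻¹; a second-order
polynomial background is fitted to the window flanks and subtracted before
(or a constant offset co-fitted with) the Lorentzian peak fit.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

__all__ = [
    "G_BAND_WINDOW",
    "TWOD_BAND_WINDOW",
    "SIGMA_FLOOR",
    "RamanSpectrum",
    "PeakFit",
    "DispersionCurve",
    "read_spectrum",
    "write_spectrum",
    "subtract_background",
    "fit_lorentzian_peak",
    "build_dispersion",
]

#: Background/fit windows (cm⁻¹) for the two principal graphene bands.
G_BAND_WINDOW = (1550.0, 1680.0)
TWOD_BAND_WINDOW = (2600.0, 2830.0)

#: Replicate-measurement error floor on extracted peak centers (cm⁻¹).
SIGMA_FLOOR = 0.4

#: Half-width (cm⁻¹) of the peak core excluded from the flank baseline fit.
DEFAULT_EXCLUSION = {"G": 40.0, "2D": 60.0}


@dataclass
class RamanSpectrum:
    """A single Raman trace with acquisition metadata.

    ``wavenumber`` must be strictly increasing and congruent with
    ``intensity`` (length ≥ 8, all finite). ``bias`` is the applied gate
    voltage V_G during acquisition, if any.
    """

    wavenumber: np.ndarray
    intensity: np.ndarray
    bias: float | None = None
    laser_wavelength: float = 532.0
    label: str = ""

    def __post_init__(self) -> None:
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavenumber.ndim != 1 or self.wavenumber.shape != self.intensity.shape:
            raise ValueError("wavenumber and intensity must be congruent 1-D arrays")
        if self.wavenumber.size < 8:
            raise ValueError("spectrum needs at least 8 points")
        if not (np.all(np.isfinite(self.wavenumber)) and np.all(np.isfinite(self.intensity))):
            raise ValueError("spectrum contains non-finite values")
        if np.any(np.diff(self.wavenumber) <= 0):
            raise ValueError("wavenumber must be strictly increasing (no duplicates)")
        if self.bias is not None and not np.isfinite(self.bias):
            raise ValueError("bias must be finite")

    def __len__(self) -> int:
        return self.wavenumber.size

    def crop(self, window: tuple[float, float]) -> "RamanSpectrum":
        """Restrict to wavenumbers in ``[lo, hi]`` (inclusive)."""
        lo, hi = window
        m = (self.wavenumber >= lo) & (self.wavenumber <= hi)
        if m.sum() < 8:
            raise ValueError(f"window {window} leaves fewer than 8 points")
        return replace(self, wavenumber=self.wavenumber[m], intensity=self.intensity[m])


@dataclass
class PeakFit:
    """Result of a single Lorentzian peak fit."""

    center: float
    center_sd: float
    fwhm: float
    amplitude: float
    offset: float
    baseline_coeffs: np.ndarray
    window: tuple[float, float]
    rmse: float
    converged: bool

    def __post_init__(self) -> None:
        if self.converged:
            if not self.fwhm > 0:
                raise ValueError("fwhm must be positive")
            if not (self.window[0] < self.center < self.window[1]):
                raise ValueError("fitted center outside the fit window")
        if self.rmse < 0:
            raise ValueError("rmse must be nonnegative")


@dataclass
class DispersionCurve:
    """ω_G versus V_G point set with per-point uncertainties.

    ``points`` rows are (bias V, center cm⁻¹, sigma cm⁻¹), sorted by bias.
    """

    bias: np.ndarray
    omega: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.bias = np.asarray(self.bias, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (self.bias.shape == self.omega.shape == self.sigma.shape):
            raise ValueError("bias, omega and sigma must be congruent")
        if self.bias.size < 4:
            raise ValueError("dispersion curve needs at least 4 points")
        if np.unique(self.bias).size != self.bias.size:
            raise ValueError("biases must be distinct")
        if not np.all(self.sigma > 0):
            raise ValueError("sigmas must be positive")
        order = np.argsort(self.bias)
        self.bias = self.bias[order]
        self.omega = self.omega[order]
        self.sigma = self.sigma[order]

    def __len__(self) -> int:
        return self.bias.size

    @classmethod
    def from_table(cls, table) -> "DispersionCurve":
        """Build from an (n, 3) array or DataFrame of (V_G, ω_G, σ)."""
        arr = np.asarray(table, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError("expected a 3-column (bias, omega, sigma) table")
        return cls(arr[:, 0], arr[:, 1], arr[:, 2])

    def to_table(self) -> np.ndarray:
        return np.column_stack([self.bias, self.omega, self.sigma])


# ---------------------------------------------------------------------------
# I/O

def read_spectrum(path, *, bias: float | None = None, laser_wavelength: float = 532.0,
                  label: str = "") -> RamanSpectrum:
    """Read a two-column text spectrum file.

    Lines beginning with ``#`` are comments; columns may be separated by
    whitespace or commas. A comment of the form ``# bias_V = -0.05`` sets
    the acquisition bias when the ``bias`` argument is None. Rows are
    sorted by wavenumber; duplicated wavenumbers are an error.
    """
    rows = []
    with open(path, "rt", encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            if "#" in line and bias is None:
                comment = line.split("#", 1)[1]
                if "bias_V" in comment and "=" in comment:
                    try:
                        bias = float(comment.split("=", 1)[1])
                    except ValueError:
                        pass
            stripped = line.split("#", 1)[0].strip()
            if not stripped:
                continue
            parts = stripped.replace(",", " ").split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected two numeric columns, got {line!r}")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed row {line!r}") from exc
    if len(rows) < 8:
        raise ValueError(f"{path}: fewer than 8 data rows")
    arr = np.array(rows, dtype=float)
    arr = arr[np.argsort(arr[:, 0], kind="stable")]
    if np.any(np.diff(arr[:, 0]) == 0):
        raise ValueError(f"{path}: duplicated wavenumber values")
    return RamanSpectrum(arr[:, 0], arr[:, 1], bias=bias,
                         laser_wavelength=laser_wavelength,
                         label=label or os.path.basename(str(path)))


def write_spectrum(spectrum: RamanSpectrum, path) -> None:
    """Write a spectrum in the two-column text format read_spectrum reads."""
    header = ["wavenumber_cm-1 intensity_counts"]
    if spectrum.bias is not None:
        header.append(f"bias_V = {spectrum.bias:.6g}")
    header.append(f"laser_nm = {spectrum.laser_wavelength:.6g}")
    np.savetxt(path, np.column_stack([spectrum.wavenumber, spectrum.intensity]),
               fmt="%.6f %.8e", header="\n".join(header))


# ---------------------------------------------------------------------------
# Background subtraction

def _flank_mask(w: np.ndarray, i: np.ndarray, exclusion_half_width: float) -> np.ndarray:
    peak_w = w[np.argmax(i)]
    return np.abs(w - peak_w) > exclusion_half_width


def subtract_background(spectrum: RamanSpectrum, window: tuple[float, float],
                        order: int = 2,
                        exclusion_half_width: float = 40.0,
                        max_iter: int = 10) -> RamanSpectrum:
    """Polynomial background removal inside a spectral window.

    The spectrum is cropped to ``window`` and a polynomial of the given
    order (≤ 2) is least-squares fitted to the flank points — those
    farther than ``exclusion_half_width`` from the running intensity
    maximum — and subtracted. Because a Lorentzian's tails reach well into
    any flank that fits inside the narrow band windows, the flank estimate
    is then refined: a Lorentzian is fitted to the flattened window and
    the polynomial refitted on the peak-subtracted signal over the whole
    window, iterating to convergence. On a peak-free window the refinement
    is skipped and the plain flank fit is returned.
    """
    if order not in (0, 1, 2):
        raise ValueError("order must be 0, 1 or 2")
    lo, hi = window
    if lo >= hi:
        raise ValueError("window must satisfy lo < hi")
    if lo < spectrum.wavenumber[0] or hi > spectrum.wavenumber[-1]:
        raise ValueError(f"window {window} outside the spectrum range "
                         f"({spectrum.wavenumber[0]:.1f}, {spectrum.wavenumber[-1]:.1f})")
    sub = spectrum.crop(window)
    w, y = sub.wavenumber, sub.intensity
    mask = _flank_mask(w, y, exclusion_half_width)
    if mask.sum() <= order:
        raise ValueError("all points excluded from the flank baseline fit; "
                         "reduce exclusion_half_width")
    w0 = w.mean()  # centered abscissa for conditioning
    coeffs = np.polyfit(w[mask] - w0, y[mask], order)
    baseline = np.polyval(coeffs, w - w0)

    refined = _joint_peak_baseline(w - w0, y, order)
    if refined is not None:
        baseline = refined
    return replace(sub, intensity=y - baseline)


def _joint_peak_baseline(x: np.ndarray, y: np.ndarray, order: int) -> np.ndarray | None:
    """Refine the baseline by co-fitting the peak with the polynomial.

    Fits Lorentzian + polynomial jointly over the whole window so the
    peak's tails stop contaminating the baseline estimate. The polynomial
    is parameterised on the abscissa rescaled to [−1, 1] for conditioning,
    and initialised from a line through the window end points (where the
    tails are smallest) rather than the flank fit, whose one-sided
    extrapolation can be arbitrarily bad. Returns the evaluated baseline,
    or None when no peak is resolvable (the flank fit is then already
    correct).
    """
    half = 0.5 * float(x[-1] - x[0])
    u = x / half  # ≈ [-1, 1]
    m = min(10, max(3, x.size // 10))
    y_lo, y_hi = float(np.median(y[:m])), float(np.median(y[-m:]))
    slope0 = 0.5 * (y_hi - y_lo)
    inter0 = 0.5 * (y_hi + y_lo)
    resid0 = y - (inter0 + slope0 * u)
    imax = int(np.argmax(resid0))
    a0 = float(resid0[imax])
    if imax in (0, y.size - 1) or a0 <= 0:
        return None

    def model(uu, center, fwhm, amplitude, *poly):
        return _lorentzian(uu * half, center * half, fwhm, amplitude, 0.0) + np.polyval(poly, uu)

    poly0 = np.zeros(order + 1)
    poly0[-1] = inter0
    if order >= 1:
        poly0[-2] = slope0
    p0 = [float(u[imax]), min(15.0, half / 2.0), a0, *poly0]
    try:
        popt, _ = curve_fit(model, u, y, p0=p0, maxfev=20000)
    except (RuntimeError, ValueError):
        return None
    center, fwhm, amplitude = popt[0] * half, abs(popt[1]), popt[2]
    if not (x[0] < center < x[-1]) or fwhm > half or amplitude <= 0:
        return None  # degenerate co-fit: trust the plain flank estimate
    return np.polyval(popt[3:], u)


# ---------------------------------------------------------------------------
# Lorentzian peak fitting

def _lorentzian(w, center, fwhm, amplitude, offset):
    half = 0.5 * fwhm
    return amplitude * half * half / ((w - center) ** 2 + half * half) + offset


def fit_lorentzian_peak(spectrum: RamanSpectrum, window: tuple[float, float],
                        *, with_offset: bool = True) -> PeakFit:
    """Least-squares Lorentzian fit of the dominant peak in a window.

    The lineshape is height-parameterised,
    ``L(ω) = A (Γ/2)² / ((ω − ω₀)² + (Γ/2)²)`` plus an optional constant
    offset (on by default, for robustness to imperfect background
    removal). Initial guesses: center at the window argmax, amplitude
    max − min, FWHM 15 cm⁻¹. The center standard deviation comes from the
    fit covariance.
    """
    sub = spectrum.crop(window)
    w, y = sub.wavenumber, sub.intensity
    # locate the peak on a lightly smoothed trace so single noisy samples
    # at the window edge do not masquerade as the maximum
    k = min(5, y.size)
    kernel = np.ones(k) / k
    y_smooth = np.convolve(np.pad(y, k // 2, mode="edge"), kernel, mode="valid")
    imax = int(np.argmax(y_smooth))
    if imax in (0, y.size - 1):
        raise ValueError("no interior intensity maximum in the fit window")
    med = float(np.median(y))
    robust_sd = 1.4826 * float(np.median(np.abs(y - med)))
    if y.max() - med <= 3.0 * robust_sd or y.max() == y.min():
        raise ValueError("no significant intensity maximum in the fit window")
    c0 = float(w[imax])
    a0 = float(y.max() - y.min())
    off0 = float(y.min()) if with_offset else 0.0
    fwhm0 = min(15.0, (w[-1] - w[0]) / 4.0)
    p0 = [c0, fwhm0, a0, off0]

    def model(x, center, fwhm, amplitude, offset):
        return _lorentzian(x, center, fwhm, amplitude, offset)

    if with_offset:
        fitfun, p_init = model, p0
    else:
        fitfun = lambda x, center, fwhm, amplitude: _lorentzian(x, center, fwhm, amplitude, 0.0)
        p_init = p0[:3]

    try:
        with warnings.catch_warnings():
            # noiseless data fit exactly: the covariance is legitimately singular
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, pcov = curve_fit(fitfun, w, y, p0=p_init, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise RuntimeError(f"Lorentzian fit did not converge in window {window}") from exc

    center, fwhm, amplitude = popt[0], abs(popt[1]), popt[2]
    offset = popt[3] if with_offset else 0.0
    if amplitude <= 0:
        raise RuntimeError("Lorentzian fit returned a non-positive amplitude")
    if not (window[0] < center < window[1]):
        raise RuntimeError("fitted peak center escaped the fit window")
    resid = y - fitfun(w, *popt)
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    center_sd = float(np.sqrt(pcov[0, 0])) if np.all(np.isfinite(pcov)) else float("nan")
    return PeakFit(center=float(center), center_sd=center_sd, fwhm=float(fwhm),
                   amplitude=float(amplitude), offset=float(offset),
                   baseline_coeffs=np.zeros(0), window=window, rmse=rmse, converged=True)


def fit_band(spectrum: RamanSpectrum, band: str = "G", *, order: int = 2,
             with_offset: bool = True) -> PeakFit:
    """Background-subtract and Lorentzian-fit one of the named bands."""
    if band == "G":
        window, excl = G_BAND_WINDOW, DEFAULT_EXCLUSION["G"]
    elif band == "2D":
        window, excl = TWOD_BAND_WINDOW, DEFAULT_EXCLUSION["2D"]
    else:
        raise ValueError("band must be 'G' or '2D'")
    flat = subtract_background(spectrum, window, order=order, exclusion_half_width=excl)
    return fit_lorentzian_peak(flat, window, with_offset=with_offset)


def build_dispersion(spectra: Iterable[RamanSpectrum], band: str = "G",
                     *, sigma_floor: float = SIGMA_FLOOR) -> DispersionCurve:
    """Extract a (V_G, ω, σ) dispersion curve from a set of biased spectra.

    Every spectrum must carry a distinct bias. σ per point is the fit
    covariance standard deviation clipped up to the replicate-based floor
    (0.4 cm⁻¹ by default). Points come out ordered by bias.
    """
    spectra = list(spectra)
    biases, centers, sigmas = [], [], []
    for spec in spectra:
        if spec.bias is None:
            raise ValueError(f"spectrum {spec.label!r} has no bias set")
        try:
            fit = fit_band(spec, band)
        except (ValueError, RuntimeError) as exc:
            raise RuntimeError(f"peak fit failed at bias {spec.bias:+.3f} V: {exc}") from exc
        biases.append(spec.bias)
        centers.append(fit.center)
        sd = fit.center_sd if np.isfinite(fit.center_sd) else 0.0
        sigmas.append(max(sd, sigma_floor))
    if len(set(biases)) != len(biases):
        raise ValueError("two spectra share the same bias")
    return DispersionCurve(np.array(biases), np.array(centers), np.array(sigmas))
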