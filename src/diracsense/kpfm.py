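"""Kelvin-probe surface-potential-difference (SPD) analysis.

A KPFM scan yields a 2D surface-potential map spanning the interface
between a bare-gold reference region and the biofunctionalised region.
Because airborne contamination drifts the absolute gold potential between
scans, every map is first zeroed so the reference-region mean is 0 mV;
the biolayer potential is then the center of a Gaussian fitted to the
histogram of masked pixels, and SPD = SP_bio − SP_Au reduces to that
center. Shifts ΔSPD across incubation steps corroborate the Raman ΔCNP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit

from .assay import ShiftEstimate

__all__ = [
    "SPMap",
    "HistogramFit",
    "SPDResult",
    "zero_reference",
    "fit_sp_histogram",
    "spd",
    "delta_spd",
    "read_sp_map",
    "write_sp_map",
]

#: Default histogram bin width in mV.
DEFAULT_BIN_WIDTH = 2.0

#: Gaussian-fit RMSE above this fraction of the peak count flags a
#: non-Gaussian (e.g. bimodal) pixel distribution.
_NON_GAUSSIAN_RMSE_FRACTION = 0.10


@dataclass
class SPMap:
    """A surface-potential grid (mV) with reference and biolayer masks."""

    potential: np.ndarray
    mask_reference: np.ndarray
    mask_biolayer: np.ndarray
    pixel_size: float = 90.0 / 256  # µm, a 90 µm frame at 256 px
    label: str = ""

    def __post_init__(self) -> None:
        self.potential = np.asarray(self.potential, dtype=float)
        self.mask_reference = np.asarray(self.mask_reference, dtype=bool)
        self.mask_biolayer = np.asarray(self.mask_biolayer, dtype=bool)
        if self.potential.ndim != 2:
            raise ValueError("potential must be a 2D grid")
        if not (self.potential.shape == self.mask_reference.shape == self.mask_biolayer.shape):
            raise ValueError("masks must be congruent with the potential grid")
        if not np.all(np.isfinite(self.potential)):
            raise ValueError("potential contains non-finite values")
        if np.any(self.mask_reference & self.mask_biolayer):
            raise ValueError("reference and biolayer masks overlap")
        if not self.mask_reference.any():
            raise ValueError("reference mask is empty")
        if not self.mask_biolayer.any():
            raise ValueError("biolayer mask is empty")


@dataclass(frozen=True)
class HistogramFit:
    """Gaussian fit of a masked-pixel potential histogram."""

    center: float
    center_sd: float
    width: float          # Gaussian sigma, mV
    bin_edges: np.ndarray
    counts: np.ndarray
    rmse: float
    gaussian_ok: bool     # False when the residuals suggest a non-Gaussian shape


@dataclass(frozen=True)
class SPDResult:
    """Surface potential difference summary of one zeroed map."""

    sp_reference_mean: float
    sp_biolayer: float
    sp_biolayer_sd: float
    histogram: HistogramFit
    label: str = ""

    @property
    def spd(self) -> float:
        return self.sp_biolayer - self.sp_reference_mean

    @property
    def spd_sd(self) -> float:
        return self.sp_biolayer_sd


def zero_reference(sp_map: SPMap) -> SPMap:
    """Subtract a constant so the reference-region mean is exactly 0 mV.

    Idempotent; relative contrasts are untouched.
    """
    offset = float(sp_map.potential[sp_map.mask_reference].mean())
    return replace(sp_map, potential=sp_map.potential - offset)


def _gaussian(x, center, sigma, amplitude):
    return amplitude * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def fit_sp_histogram(sp_map: SPMap, mask: np.ndarray,
                     bin_width: float = DEFAULT_BIN_WIDTH) -> HistogramFit:
    """Histogram the masked pixels and fit a Gaussian to the bin counts.

    Initialised from the sample mean and sd; the center uncertainty is the
    covariance standard error of the fitted center. A fit whose RMSE
    exceeds 10 % of the peak count is flagged ``gaussian_ok=False`` (the
    signature of a bimodal mask spanning both regions).
    """
    values = sp_map.potential[np.asarray(mask, dtype=bool)]
    if values.size < 100:
        raise ValueError("need at least 100 masked pixels for a histogram fit")
    if np.ptp(values) == 0:
        raise ValueError("degenerate mask: all pixels equal")
    lo, hi = values.min(), values.max()
    n_bins = max(int(math.ceil((hi - lo) / bin_width)), 5)
    counts, edges = np.histogram(values, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p0 = [float(values.mean()), max(float(values.std()), bin_width), float(counts.max())]
    try:
        popt, pcov = curve_fit(_gaussian, centers, counts, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError("Gaussian histogram fit did not converge") from exc
    center, sigma, amp = float(popt[0]), abs(float(popt[1])), float(popt[2])
    resid = counts - _gaussian(centers, *popt)
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    center_sd = float(np.sqrt(pcov[0, 0])) if np.all(np.isfinite(pcov)) else float("nan")
    ok = rmse <= _NON_GAUSSIAN_RMSE_FRACTION * max(amp, 1e-12)
    return HistogramFit(center=center, center_sd=center_sd, width=sigma,
                        bin_edges=edges, counts=counts, rmse=rmse, gaussian_ok=ok)


def spd(sp_map: SPMap, bin_width: float = DEFAULT_BIN_WIDTH) -> SPDResult:
    """SPD of a map: zero the reference, Gaussian-fit the biolayer pixels.

    After zeroing, SP_Au = 0 by construction, so SPD equals the biolayer
    Gaussian center. The reported sd is the width of the fitted Gaussian
    (the pixel-to-pixel dispersion), matching how SPD uncertainties are
    quoted for potential maps; the center standard error is available on
    the embedded :class:`HistogramFit`.
    """
    zeroed = zero_reference(sp_map)
    hist = fit_sp_histogram(zeroed, zeroed.mask_biolayer, bin_width=bin_width)
    ref_mean = float(zeroed.potential[zeroed.mask_reference].mean())
    return SPDResult(sp_reference_mean=ref_mean, sp_biolayer=hist.center,
                     sp_biolayer_sd=hist.width, histogram=hist, label=sp_map.label)


def delta_spd(baseline: SPDResult, step: SPDResult) -> ShiftEstimate:
    """ΔSPD (mV) between two incubation steps, quadrature sd."""
    value = step.spd - baseline.spd
    sd = math.hypot(step.spd_sd, baseline.spd_sd)
    return ShiftEstimate(value, sd)


# ---------------------------------------------------------------------------
# Plain-text map I/O: the grid as a whitespace matrix; masks as half-plane
# metadata in the header (column index splitting reference | biolayer).

def write_sp_map(sp_map: SPMap, path) -> None:
    """Write a map whose masks are vertical half-planes as a text matrix."""
    ref_cols = np.where(sp_map.mask_reference.all(axis=0))[0]
    bio_cols = np.where(sp_map.mask_biolayer.all(axis=0))[0]
    if ref_cols.size == 0 or bio_cols.size == 0:
        raise ValueError("only half-plane-masked maps can be serialised")
    split = int(max(ref_cols)) + 1 if max(ref_cols) < min(bio_cols) else int(max(bio_cols)) + 1
    order = "ref_left" if max(ref_cols) < min(bio_cols) else "bio_left"
    header = (f"surface potential map (mV)\nsplit_col = {split}\norder = {order}\n"
              f"pixel_size_um = {sp_map.pixel_size:.6g}")
    np.savetxt(path, sp_map.potential, fmt="%.4f", header=header)


def read_sp_map(path, label: str = "") -> SPMap:
    """Read a half-plane map written by :func:`write_sp_map`."""
    split = order = pixel = None
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            text = line[1:].strip()
            if text.startswith("split_col"):
                split = int(text.split("=")[1])
            elif text.startswith("order"):
                order = text.split("=")[1].strip()
            elif text.startswith("pixel_size_um"):
                pixel = float(text.split("=")[1])
    if split is None or order not in ("ref_left", "bio_left"):
        raise ValueError(f"{path}: missing or malformed mask metadata header")
    grid = np.loadtxt(path)
    cols = np.arange(grid.shape[1])
    left = np.broadcast_to(cols < split, grid.shape)
    if order == "ref_left":
        ref, bio = left, ~left
    else:
        bio, ref = left, ~left
    return SPMap(grid, mask_reference=ref.copy(), mask_biolayer=bio.copy(),
                 pixel_size=pixel if pixel else 90.0 / max(grid.shape), label=label)
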