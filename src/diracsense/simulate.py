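"""Synthetic instrument data for the full sensing pipeline.

Generates everything the analysis consumes — bias-swept Raman spectra,
assay series (baseline, blanks, negative controls, sensing steps) and
KPFM surface-potential maps — from explicit ground-truth parameters, so
every stage can be tested end to end without instrument data.

The forward model mirrors the analysis model: Lorentzian G and 2D peaks
on a second-order polynomial baseline with additive Gaussian intensity
noise; the G-peak center follows the gating model at the spectrum's bias,
and the 2D center moves at 14/20 of the G shift (the ratio of the two
bands' observed voltage sensitivities; no microscopic 2D law is
modelled). The intensity-noise amplitude is a stored constant calibrated
once so that fitted G-peak centers scatter by ≈0.4 cm⁻¹ — the
replicate-to-replicate error a stepped-bias measurement shows.

Everything is deterministic under ``ScenarioConfig.seed``: each artefact
derives an independent child generator from the seed and a stable
structural index, so regenerating any piece in isolation reproduces it
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .cnp import CNPFitResult
from .gating import GatingParams, expected_molecules, predict_g_peak
from .kpfm import SPMap
from .spectra import DispersionCurve, RamanSpectrum

__all__ = ["ScenarioConfig", "SpectrumShape", "AssayDesign", "KPFMDesign",
           "make_spectrum", "make_sweep", "make_assay", "make_kpfm_map",
           "make_kpfm_series", "AssaySimulation"]

#: Intensity-noise sd (counts) calibrated so the fitted G-center scatter is
#: ≈0.4 cm⁻¹ at the default peak shape (amplitude 1000, FWHM 15, 1 cm⁻¹ grid).
CALIBRATED_NOISE_SD = 130.0

#: Fraction of the G-band voltage sensitivity carried by the 2D band
#: (≈14 vs ≈20 cm⁻¹ V⁻¹).
TWOD_SHIFT_RATIO = 14.0 / 20.0


@dataclass(frozen=True)
class SpectrumShape:
    """Peak amplitudes/widths, baseline polynomial and noise of one trace."""

    grid_start: float = 1450.0
    grid_stop: float = 2950.0
    grid_step: float = 1.0
    g_amplitude: float = 1000.0
    g_fwhm: float = 15.0
    twod_center0: float = 2690.0
    twod_amplitude: float = 2000.0
    twod_fwhm: float = 30.0
    baseline_coeffs: tuple[float, ...] = (2e-5, 0.05, 200.0)  # quadratic in (ω − 2000)
    noise_sd: float = CALIBRATED_NOISE_SD

    def baseline(self, w: np.ndarray) -> np.ndarray:
        return np.polyval(self.baseline_coeffs, w - 2000.0)


@dataclass(frozen=True)
class AssayDesign:
    """Step layout and ground-truth CNP trajectory of one assay replicate.

    The binder response is a saturating step: every sensing dose from the
    lowest concentration up shifts the true CNP by ``binder_shift``
    (concentration-independent); blanks and non-binding negative controls
    leave the true CNP at baseline apart from a Gaussian jitter.
    """

    binder_shift: float = -0.055           # V, saturating sensing response
    jitter_sd: float = 0.011               # V, blank/control CNP jitter
    n_blanks: int = 3
    sensing_concentrations: tuple[float, ...] = (1e-19, 1e-18, 1e-17, 1e-16, 1e-13, 1e-10)
    control_concentrations: tuple[float, ...] = (1e-16, 1e-13, 1e-10)
    analyte: str = "IgM"
    control_analyte: str = "IgG"
    volume_l: float = 1e-4                 # incubation volume, 0.1 mL


@dataclass(frozen=True)
class KPFMDesign:
    """Map geometry and noise for synthetic KPFM scans."""

    map_size: int = 256                    # pixels per side; 90 µm frame
    frame_um: float = 90.0
    noise_sd: float = 15.0                 # mV per pixel
    spd_baseline: float = -0.0             # mV, pristine biolayer vs gold
    spd_shift: float = -66.0               # mV, SPD change on binding
    contamination_sd: float = 50.0         # mV, global gold-potential drift


@dataclass(frozen=True)
class ScenarioConfig:
    """Ground truth for a complete simulated experiment."""

    gating: GatingParams = field(
        default_factory=lambda: GatingParams(v_cnp=0.335, areal_capacitance=5.26e-2))
    sweep_start: float = 0.0
    sweep_stop: float = -0.5
    sweep_step: float = -0.05
    spectrum: SpectrumShape = field(default_factory=SpectrumShape)
    assay: AssayDesign = field(default_factory=AssayDesign)
    kpfm: KPFMDesign = field(default_factory=KPFMDesign)
    seed: int = 20250121

    @property
    def sweep_grid(self) -> np.ndarray:
        n = int(round((self.sweep_stop - self.sweep_start) / self.sweep_step)) + 1
        return self.sweep_start + self.sweep_step * np.arange(n)

    def rng(self, *index: int) -> np.random.Generator:
        """Child generator keyed by the config seed and a structural index."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=index))


def _lorentz(w: np.ndarray, center: float, fwhm: float, amplitude: float) -> np.ndarray:
    half = 0.5 * fwhm
    return amplitude * half * half / ((w - center) ** 2 + half * half)


def make_spectrum(config: ScenarioConfig, bias: float,
                  gating: GatingParams | None = None,
                  rng: np.random.Generator | None = None,
                  noise_sd: float | None = None,
                  label: str = "") -> RamanSpectrum:
    """One synthetic spectrum at the given bias.

    The G center is ``predict_g_peak(bias, truth)``; the 2D center moves at
    :data:`TWOD_SHIFT_RATIO` of the G shift. ``noise_sd`` overrides the
    configured intensity noise (0 gives a noiseless trace); ``rng`` defaults
    to a child stream keyed on the bias grid index.
    """
    shape = config.spectrum
    truth = gating if gating is not None else config.gating
    if rng is None:
        rng = config.rng(0, int(round(bias * 1e4)) & 0xFFFF)
    sd = shape.noise_sd if noise_sd is None else noise_sd
    w = np.arange(shape.grid_start, shape.grid_stop + 0.5 * shape.grid_step, shape.grid_step)
    g_center = predict_g_peak(bias, truth)
    twod_center = shape.twod_center0 + TWOD_SHIFT_RATIO * (g_center - truth.omega_g0)
    y = (_lorentz(w, g_center, shape.g_fwhm, shape.g_amplitude)
         + _lorentz(w, twod_center, shape.twod_fwhm, shape.twod_amplitude)
         + shape.baseline(w))
    if sd > 0:
        y = y + rng.normal(0.0, sd, w.size)
    return RamanSpectrum(w, y, bias=bias, label=label or f"V_G={bias:+.3f}V")


def make_sweep(config: ScenarioConfig,
               gating: GatingParams | None = None,
               noise_sd: float | None = None,
               rng: np.random.Generator | None = None,
               label: str = "") -> list[RamanSpectrum]:
    """One spectrum per bias of the voltage sweep grid (11 by default)."""
    truth = gating if gating is not None else config.gating
    if rng is None:
        rng = config.rng(1)
    return [make_spectrum(config, float(b), gating=truth, rng=rng,
                          noise_sd=noise_sd, label=f"{label}V_G={b:+.3f}V")
            for b in config.sweep_grid]


def true_dispersion(config: ScenarioConfig,
                    gating: GatingParams | None = None,
                    sigma: float = 0.4) -> DispersionCurve:
    """The noiseless (V_G, ω_G, σ) curve implied by the ground truth."""
    truth = gating if gating is not None else config.gating
    grid = config.sweep_grid
    return DispersionCurve(grid, predict_g_peak(grid, truth), np.full(grid.size, sigma))


# ---------------------------------------------------------------------------
# Assay series

@dataclass
class AssayStepTruth:
    """Manifest row of one simulated incubation step with its ground truth."""

    step_index: int
    label: str               # baseline | blank | negative_control | sensing
    analyte: str
    concentration: float
    true_v_cnp: float
    replicate_id: str = "rep1"


@dataclass
class AssaySimulation:
    """A simulated assay: manifest plus per-step data access.

    ``mode='cnp'`` exposes the idealised read-out (the true per-step CNP,
    wrapped as fit results with the nominal jitter sd) and is cheap enough
    for large Monte-Carlo studies; ``mode='spectra'`` generates the full
    per-step voltage sweeps for end-to-end runs through the Raman chain.
    """

    config: ScenarioConfig
    steps: list[AssayStepTruth]

    @property
    def manifest(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(s) for s in self.steps])
        volume = self.config.assay.volume_l
        df["expected_molecules"] = [
            expected_molecules(c, volume)[0] if c > 0 else 0.0
            for c in df["concentration"]
        ]
        return df

    def sweep(self, step: AssayStepTruth, noise_sd: float | None = None
              ) -> list[RamanSpectrum]:
        gating = replace(self.config.gating, v_cnp=step.true_v_cnp)
        rng = self.config.rng(2, step.step_index)
        return make_sweep(self.config, gating=gating, noise_sd=noise_sd, rng=rng,
                          label=f"step{step.step_index}:")

    def cnp_readout(self, step: AssayStepTruth) -> CNPFitResult:
        """Idealised CNP read-out: truth value, nominal jitter sd."""
        return CNPFitResult.from_values(step.true_v_cnp, self.config.assay.jitter_sd)


def make_assay(config: ScenarioConfig, replicate_id: str = "rep1") -> AssaySimulation:
    """Simulate one assay replicate's step sequence and CNP trajectory.

    Default layout: 1 baseline, 3 blanks, 3 negative-control (non-binding
    analyte) steps and 6 sensing steps spanning 10⁻¹⁹–10⁻¹⁰ M. Sensing
    steps shift the true CNP by the configured binder shift from the
    lowest dose onward; blanks and controls jitter around baseline with
    the configured sd.
    """
    design = config.assay
    rng = config.rng(3)
    v0 = config.gating.v_cnp
    steps = [AssayStepTruth(0, "baseline", "", 0.0, v0, replicate_id)]
    idx = 1
    for _ in range(design.n_blanks):
        steps.append(AssayStepTruth(idx, "blank", "", 0.0,
                                    v0 + rng.normal(0.0, design.jitter_sd), replicate_id))
        idx += 1
    for conc in design.control_concentrations:
        steps.append(AssayStepTruth(idx, "negative_control", design.control_analyte, conc,
                                    v0 + rng.normal(0.0, design.jitter_sd), replicate_id))
        idx += 1
    for conc in design.sensing_concentrations:
        steps.append(AssayStepTruth(idx, "sensing", design.analyte, conc,
                                    v0 + design.binder_shift, replicate_id))
        idx += 1
    return AssaySimulation(config=config, steps=steps)


# ---------------------------------------------------------------------------
# KPFM maps

def make_kpfm_map(config: ScenarioConfig, spd: float,
                  rng: np.random.Generator | None = None,
                  contamination: float | None = None,
                  label: str = "") -> SPMap:
    """Two-region synthetic surface-potential map with a prescribed SPD.

    Left half: bare-gold reference; right half: biolayer offset by ``spd``
    (mV). Gaussian pixel noise everywhere, plus a global offset emulating
    the airborne-contamination drift of the absolute gold potential
    (drawn from the configured sd unless given explicitly).
    """
    design = config.kpfm
    if rng is None:
        rng = config.rng(4)
    n = design.map_size
    drift = rng.normal(0.0, design.contamination_sd) if contamination is None else contamination
    grid = rng.normal(0.0, design.noise_sd, (n, n)) + drift
    cols = np.arange(n)
    bio = np.broadcast_to(cols >= n // 2, (n, n)).copy()
    grid = grid + np.where(bio, spd, 0.0)
    return SPMap(grid, mask_reference=~bio, mask_biolayer=bio,
                 pixel_size=design.frame_um / n, label=label)


def make_kpfm_series(config: ScenarioConfig,
                     concentrations: Sequence[float] = (1e-19, 1e-17, 1e-16)
                     ) -> list[tuple[str, float, SPMap]]:
    """Baseline map plus one map per sensing concentration.

    Returns (label, concentration, map) tuples; sensing maps carry the
    configured saturating SPD shift relative to the baseline SPD.
    """
    design = config.kpfm
    out = [("baseline", 0.0,
            make_kpfm_map(config, design.spd_baseline, rng=config.rng(5, 0),
                          label="baseline"))]
    for i, conc in enumerate(concentrations, start=1):
        out.append(("sensing", conc,
                    make_kpfm_map(config, design.spd_baseline + design.spd_shift,
                                  rng=config.rng(5, i), label=f"IgM {conc:g} M")))
    return out
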