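# Methods

## Physical model

The device is a two-terminal cell: a biofunctionalised gold electrode and a
bare graphene electrode coupled through an electrolyte. All interfacial
capacitances (gold/water and water/graphene double layers, graphene quantum
capacitance) are lumped into a single series gate capacitance C_gate; the
electrolyte resistance is irrelevant in the steady state at which spectra
are taken, and the cell is operated inside the electrochemically inert bias
window, so no Faradaic pathway is modelled. Only the areal combination
c = C_gate/A_g enters the electrostatics; the total C_gate is reported by
multiplying the fitted c with a configured contact area A_g.

Charge balance relates the applied bias to the graphene Fermi level,

    V_G − V_CNP = E_F/e + sign(E_F)·e·n/c,   n = (|E_F|/ħv_F)²/π,

with V_CNP the charge-neutrality-point voltage fixed by the initial doping
(V_CNP = n_dop·e/c). Eliminating n gives a quadratic in |E_F| whose
positive root, signed by V_G − V_CNP, is implemented in closed form
(`gating.fermi_level`) and validated in the tests against an independent
bisection solver of the defining balance to < 1e-9 eV over
(V_G, c) ∈ [−1, 1] V × [1e-3, 1] F m⁻².

The Raman G band stiffens linearly in the Fermi-level magnitude,
Δω_G = (λ_Γ/2π)·|E_F|, with |E_F| converted at 8065.54 cm⁻¹/eV. The
magnitude convention (rather than signed E_F) is deliberate: the band
blueshifts on both sides of the Dirac point and ω_G0 is the minimum at the
CNP, so the composed ω_G(V_G) is V-shaped and symmetric about V_CNP. The
linear law is quoted for |E_F| between 100 and 500 meV; outside that window
`g_peak_shift` still evaluates it (refusing would break optimisation
through the near-CNP region) but emits a `PhononValidityWarning` when
called as a public API.

### Parameters

| parameter | default | units | role |
|---|---|---|---|
| λ_Γ | 0.03 | – | electron–phonon coupling; fixed in fits |
| v_F | 1.1 × 10⁶ | m s⁻¹ | Fermi velocity; fixed |
| ω_G0 | 1580 | cm⁻¹ | G position at the CNP; fixed |
| c = C_gate/A_g | 5.26 × 10⁻² | F m⁻² | free fit parameter |
| V_CNP | device-dependent | V | free fit parameter |
| A_g | 3.270 × 10⁻⁵ | m² | reporting constant only |

A_g is not identifiable from the data (only c appears in the model); the
default is back-computed as 1.72 µF / 5.26 × 10⁻² F m⁻² so that the
reference device's areal capacitance and its total capacitance are exactly
mutually consistent. Any other area can be configured; it rescales the
reported C_gate linearly and nothing else.

## Spectrum processing

Spectra are two-column text (cm⁻¹, counts). Band windows are fixed at
1550–1680 cm⁻¹ (G) and 2600–2830 cm⁻¹ (2D). Background removal fits a
polynomial of order ≤ 2 inside the window. A pure flank fit (excluding a
±40 cm⁻¹ core around the running maximum for G, ±60 for 2D) is used to
initialise, but is not sufficient by itself: a Lorentzian of FWHM 15 cm⁻¹
still carries 3–8 % of its height at those flank distances, and for a peak
near 1589 cm⁻¹ the left flank of the G window is essentially empty, making
one-sided quadratic extrapolation noise-amplifying. The implementation
therefore refines the baseline by a joint Lorentzian + polynomial fit over
the whole window, with the polynomial basis rescaled to [−1, 1] for
conditioning; if no peak is resolvable the plain flank fit is kept (and is
then exact). On noiseless synthetic input the separation is exact to
machine precision and the operation is idempotent.

Peak fitting is an unweighted least-squares height-parameterised Lorentzian
A(Γ/2)²/((ω−ω₀)²+(Γ/2)²) plus, by default, a constant offset that absorbs
residual background (disable with `with_offset=False`). Initial guesses:
center at the (smoothed) window argmax, amplitude max − min, FWHM
15 cm⁻¹. Windows with no interior or no significant maximum (peak
prominence below 3 robust sigma of the windowed intensities) are rejected.
The center uncertainty is the covariance standard error; when building a
dispersion curve it is floored at 0.4 cm⁻¹, the replicate-to-replicate
scatter of extracted centers, so no point claims better than the
instrument's demonstrated reproducibility.

## Dispersion fitting

`DispersionModel.fit()` minimises Σ((ω_i − model(V_i))/σ_i)² over exactly
two parameters (V_CNP, c) with λ_Γ, v_F, ω_G0 held fixed, using a
trust-region least-squares optimiser restarted from five CNP offsets
around a heuristic initial guess (interior ω-minimum if present, otherwise
0.3 V beyond the low-ω end of a one-sided sweep; capacitance from matching
the end-to-end slope to the large-|E_F| √V asymptote). Weights are
absolute (σ known), so the parameter covariance is (JᵀJ)⁻¹ without χ²
rescaling and the reported CNP standard deviation is the fit-algorithm
estimate. Reduced χ² = SS/(n−2) and the unweighted RMSE are reported;
noise-free round trips recover generator truth to < 1e-6 relative and
noisy fits at the calibrated noise stay below 1 cm⁻¹ RMSE.

One-sided sweeps (the standard 0 → −0.5 V protocol on a p-doped device
with CNP ≈ +0.34 V) are accepted; the result is flagged `extrapolated`
since the minimum lies outside the scanned range. If the fitted |E_F|
stays below 20 meV across the whole sweep the capacitance is flagged
unidentifiable (the model is then locally linear and c unconstrained);
bias spans under 0.1 V warn about ill-conditioning.

## Sensing metrics

ΔCNP = CNP_step − CNP_baseline with quadrature-propagated sd. Blank
statistics report µ_n = mean |blank shift| (the average noise level) and
the sample sd σ; LOD = µ_n + 3σ and LOI = µ_n + 6σ (a bare-6σ convention
is exposed by flag, since both combinations appear in practice and the two
readings cannot be reconciled from a single reported pair). OFF/ON calls
use the magnitude with strict inequality: ON iff |ΔCNP| > LOD.

When an assay carries only a handful of blank steps, the per-run LOD
estimate is dominated by the sampling noise of a low-degrees-of-freedom
sd (a 3-blank sd fluctuates by tens of percent, and the resulting LOD
exceeds a genuine −55 mV response in roughly one run in six). The platform
is therefore characterised once against a well-sampled blank campaign:
`platform_lod(σ) = σ√(2/π) + 3σ` is the asymptotic LOD of Gaussian blank
noise (41.8 mV at σ = 11 mV), and `evaluate_assay(..., lod=...)` classifies
against that fixed line while still reporting the run's own blank
statistics. Detector-performance figures quoted by the tests use the
platform LOD; the per-run estimator remains available and is what
`evaluate_assay` defaults to.

Dose–response tables are unweighted means ± sample sd per concentration;
missing replicates are absent, not zero, and single-replicate cells are
flagged as having no defined sd. The response is qualitative and
saturating, so no calibration curve (e.g. Langmuir) is fitted. The
relative CNP shift is reported under both conventions — |Δ|/baseline
(default) and (sensing − baseline)/sensing — because the two differ
visibly (≈16 % vs ≈−20 % for a −55 mV shift from a 335 mV baseline) and
both occur in reports.

Expected molecule counts use c·N_A·V with a Poisson sd; at 10⁻¹⁹ M in
0.1 mL this is 6.0 ± 2.5 molecules — the single-molecule regime.

## KPFM analysis

Maps are 2D potential grids (mV) with disjoint reference (bare gold) and
biolayer masks, supplied explicitly (the text format stores half-plane
masks; no edge detection is attempted). Because airborne contamination
drifts the absolute gold potential between scans, each map is zeroed by
subtracting the reference-region mean (idempotent; contrasts untouched).
SP_bio is the center of a Gaussian fitted by least squares to the 2
mV-binned histogram of biolayer pixels, initialised from the sample
moments; a fit RMSE above 10 % of the peak count flags a non-Gaussian
(e.g. bimodal) distribution. After zeroing SP_Au = 0 exactly, so
SPD = SP_bio. The SPD uncertainty is quoted as the fitted Gaussian width —
the pixel-to-pixel dispersion, which is how map-level SPD uncertainties
are conventionally reported — while the (much smaller) center standard
error remains available on the histogram fit. ΔSPD across incubation
steps is a quadrature difference against the replicate's baseline map.

## Synthetic data

The generator's defaults encode the reference study conditions: 11-point
0 → −0.5 V sweeps in 0.05 V steps; device truth V_CNP = +335 mV,
c = 5.26 × 10⁻² F m⁻²; G amplitude 1000 counts, FWHM 15 cm⁻¹ on a gentle
quadratic baseline, 2D at 2690 cm⁻¹ moving at 14/20 of the G shift (a
purely phenomenological ratio of the two bands' voltage sensitivities —
no microscopic 2D law is modelled); assay series of 1 baseline, 3 blanks,
3 non-binding (IgG) controls and 6 sensing (IgM) doses from 10⁻¹⁹ to
10⁻¹⁰ M with a saturating, concentration-independent −55 mV binder shift
and 11 mV Gaussian jitter on blanks/controls; KPFM frames of 256² pixels
over 90 µm with 15 mV pixel noise, a −66 mV biolayer offset on binding
and a random global contamination offset.

The intensity-noise amplitude is a stored constant (130 counts at the
default peak shape), calibrated once so that fitted G centers scatter by
≈0.4 cm⁻¹ — the quantity the instrument specification pins — and verified
across seeds to land in 0.40–0.45 cm⁻¹.

Everything derives child RNG streams from `ScenarioConfig.seed` plus a
stable structural index, so any artefact regenerates bit-identically in
isolation. `AssaySimulation` exposes two read-outs: full per-step spectral
sweeps for end-to-end runs, and an idealised CNP read-out (truth + jitter,
nominal sd) for large Monte-Carlo studies; the latter isolates the
assay-level noise (11 mV) from the ~19 mV per-fit noise the spectral chain
adds at the calibrated noise level.

What the generator does **not** emulate: cosmic-ray spikes, wavenumber
miscalibration, the D band, photobleaching or stage drift, Faradaic
leakage, spot-to-spot graphene inhomogeneity, KPFM topography crosstalk
or within-scan drift. Passing tests therefore demonstrate correctness of
the estimators under the declared noise model, not robustness to every
instrumental pathology.

## Numerical choices and limitations

- Optimiser tolerances 1e-14 (xtol/ftol/gtol) for the dispersion fit;
  multistart over 5 CNP offsets; parameter scaling (0.1 V, ~c).
- Tie-break: |ΔCNP| exactly equal to the LOD is OFF.
- The CNP of a one-sided sweep is an extrapolation and its uncertainty
  (~19 mV at the calibrated noise with 11 points) is dominated by the
  lever arm, not the per-point error; two-sided sweeps would shrink it.
- Monte-Carlo sizes used by the test suite (500 dispersion replicates,
  100 KPFM maps, 200 assay runs) were chosen to keep Monte-Carlo error
  well below the asserted bounds.
- The estimator of V_CNP from noisy one-sided sweeps carries a small
  (< 1 mV at the calibrated noise) nonlinearity bias, far below the
  per-fit uncertainty.
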