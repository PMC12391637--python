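"""Sensing metrics for the CNP-shift immunoassay.

The analytical signal is the shift ΔCNP of the graphene charge-neutrality
point between a baseline measurement and a post-incubation measurement.
Blank incubations define the noise level; the IUPAC-style limit of
detection is the mean blank level plus three standard deviations (limit of
identification: six), and each step is called OFF or ON by comparing
|ΔCNP| against the LOD. The response is qualitative and saturating — any
dose at or above the single-molecule threshold yields an essentially
constant shift — so no calibration curve is fitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cnp import CNPFitResult

__all__ = [
    "AssayStep",
    "ShiftEstimate",
    "BlankStatistics",
    "AssayResult",
    "delta_cnp",
    "limit_of_detection",
    "limit_of_identification",
    "classify",
    "relative_shift",
    "dose_response",
    "evaluate_assay",
]

STEP_LABELS = ("baseline", "blank", "negative_control", "sensing")


@dataclass
class AssayStep:
    """One incubation step of the sensing protocol."""

    label: str
    fit: CNPFitResult
    analyte: str = ""
    concentration: float = 0.0
    replicate_id: str = "rep1"

    def __post_init__(self) -> None:
        if self.label not in STEP_LABELS:
            raise ValueError(f"label must be one of {STEP_LABELS}, got {self.label!r}")
        if self.concentration < 0:
            raise ValueError("concentration must be nonnegative")


@dataclass(frozen=True)
class ShiftEstimate:
    """A ΔCNP value in mV with its propagated standard deviation."""

    value: float
    sd: float


@dataclass(frozen=True)
class BlankStatistics:
    """Noise level (µ_n), dispersion (σ) and the derived LOD/LOI, all mV."""

    mu_n: float
    sigma: float
    n_blanks: int
    lod: float
    loi: float


def delta_cnp(baseline: CNPFitResult, step: CNPFitResult) -> ShiftEstimate:
    """CNP shift (mV): step minus baseline, with quadrature-propagated sd."""
    for name, fit in (("baseline", baseline), ("step", step)):
        if not fit.converged:
            raise ValueError(f"{name} fit did not converge; ΔCNP undefined")
    value = (step.v_cnp - baseline.v_cnp) * 1e3
    sd = math.hypot(step.v_cnp_sd * 1e3, baseline.v_cnp_sd * 1e3)
    return ShiftEstimate(value, sd)


def _blank_moments(blank_shifts: Sequence[float]) -> tuple[float, float]:
    shifts = np.asarray(blank_shifts, dtype=float)
    if shifts.size < 2:
        raise ValueError("need at least 2 blank shifts to estimate the noise level")
    mu_n = float(np.mean(np.abs(shifts)))
    sigma = float(np.std(shifts, ddof=1))
    return mu_n, sigma


def limit_of_detection(blank_shifts: Sequence[float]) -> BlankStatistics:
    """IUPAC-style LOD from blank ΔCNP values (mV).

    LOD = µ_n + 3σ with µ_n the mean magnitude of the blank shifts (the
    average noise level) and σ their sample standard deviation (n−1). The
    components are returned alongside so either convention of combining
    them can be reconstructed.
    """
    mu_n, sigma = _blank_moments(blank_shifts)
    return BlankStatistics(mu_n=mu_n, sigma=sigma, n_blanks=len(blank_shifts),
                           lod=mu_n + 3.0 * sigma, loi=mu_n + 6.0 * sigma)


def limit_of_identification(blank_shifts: Sequence[float],
                            *, pure_sigma: bool = False) -> float:
    """Limit of identification (mV): six-sigma analogue of the LOD.

    Default convention µ_n + 6σ; ``pure_sigma=True`` returns the bare 6σ
    reading instead.
    """
    mu_n, sigma = _blank_moments(blank_shifts)
    return 6.0 * sigma if pure_sigma else mu_n + 6.0 * sigma


def platform_lod(noise_sd: float) -> float:
    """Asymptotic LOD (mV) of the platform for Gaussian blank noise.

    A blank ΔCNP distribution N(0, σ) has mean magnitude σ·sqrt(2/π), so a
    well-characterised blank campaign converges to
    LOD = σ·sqrt(2/π) + 3σ. Classifying against this platform constant
    separates detector performance from the sampling noise of a small
    per-run blank set (a 3-blank sample sd has only 2 degrees of freedom
    and fluctuates by tens of percent).
    """
    if not noise_sd >= 0:
        raise ValueError("noise_sd must be nonnegative")
    return noise_sd * math.sqrt(2.0 / math.pi) + 3.0 * noise_sd


def classify(delta: float, lod: float) -> str:
    """OFF/ON call: ON iff |ΔCNP| strictly exceeds the LOD.

    The magnitude is used because sensing shifts are negative-going in
    this system; a shift exactly at the LOD is OFF.
    """
    if not lod >= 0:
        raise ValueError("lod must be nonnegative")
    return "ON" if abs(delta) > lod else "OFF"


def relative_shift(baseline: float, sensing: float) -> dict:
    """Relative CNP shift in percent, under both common conventions.

    Returns ``{"abs_over_baseline": |Δ|/baseline %, "over_sensing":
    (sensing − baseline)/sensing %}``. Reports should quote
    ``abs_over_baseline`` (the default reading of a ≈16 % shift for a
    335 → 286 mV change).
    """
    if baseline == 0 or sensing == 0:
        raise ZeroDivisionError("relative shift undefined for zero CNP")
    delta = sensing - baseline
    return {
        "abs_over_baseline": 100.0 * abs(delta) / abs(baseline),
        "over_sensing": 100.0 * delta / sensing,
    }


def dose_response(shifts_by_concentration: Mapping[float, Sequence[float]]
                  ) -> pd.DataFrame:
    """Per-concentration mean ΔCNP ± sample sd across replicates.

    Input maps concentration (M) to the replicate ΔCNP values (mV);
    missing replicates are simply absent from the lists. Groups with a
    single replicate get ``sd = NaN`` and ``sd_defined = False``.
    """
    rows = []
    for conc in sorted(shifts_by_concentration):
        vals = [v for v in shifts_by_concentration[conc] if v is not None]
        if len(vals) == 0:
            raise ValueError(f"no replicates at concentration {conc:g}")
        arr = np.asarray(vals, dtype=float)
        sd = float(np.std(arr, ddof=1)) if arr.size > 1 else float("nan")
        rows.append({"concentration": conc, "n": arr.size,
                     "mean_delta_cnp": float(arr.mean()), "sd_delta_cnp": sd,
                     "sd_defined": arr.size > 1})
    return pd.DataFrame(rows)


@dataclass
class AssayResult:
    """Full evaluation of one assay run."""

    steps: pd.DataFrame            # per-step ΔCNP, sd, call
    blank_stats: BlankStatistics
    dose_response: pd.DataFrame

    @property
    def lod(self) -> float:
        return self.blank_stats.lod

    @property
    def loi(self) -> float:
        return self.blank_stats.loi


def evaluate_assay(steps: Iterable[AssayStep], lod: float | None = None) -> AssayResult:
    """Compute ΔCNP, LOD/LOI and OFF/ON calls for a list of assay steps.

    Exactly one ``baseline`` step per replicate is required; every other
    step is differenced against its replicate's baseline. Blank steps from
    all replicates pool into the LOD estimate; sensing and
    negative-control steps are then classified against it. Passing ``lod``
    classifies against that fixed platform LOD (mV) instead — the blank
    statistics of the run are still reported when blanks are present.
    """
    steps = list(steps)
    baselines: dict[str, AssayStep] = {}
    for s in steps:
        if s.label == "baseline":
            if s.replicate_id in baselines:
                raise ValueError(f"replicate {s.replicate_id!r} has two baselines")
            baselines[s.replicate_id] = s
    rows = []
    for s in steps:
        if s.label == "baseline":
            continue
        if s.replicate_id not in baselines:
            raise ValueError(f"replicate {s.replicate_id!r} has no baseline step")
        shift = delta_cnp(baselines[s.replicate_id].fit, s.fit)
        rows.append({"replicate_id": s.replicate_id, "label": s.label,
                     "analyte": s.analyte, "concentration": s.concentration,
                     "delta_cnp_mV": shift.value, "sd_mV": shift.sd})
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("assay contains no non-baseline steps")

    blank_shifts = table.loc[table.label == "blank", "delta_cnp_mV"].to_numpy()
    if blank_shifts.size >= 2:
        stats = limit_of_detection(blank_shifts)
    elif lod is not None:
        stats = BlankStatistics(mu_n=float("nan"), sigma=float("nan"),
                                n_blanks=int(blank_shifts.size),
                                lod=lod, loi=float("nan"))
    else:
        raise ValueError("need at least 2 blank steps (or an explicit lod) "
                         "to classify OFF/ON")
    threshold = stats.lod if lod is None else lod
    table["call"] = [classify(d, threshold) for d in table["delta_cnp_mV"]]

    sensing = table[table.label == "sensing"]
    grouped = {c: g["delta_cnp_mV"].tolist()
               for c, g in sensing.groupby("concentration")}
    dr = dose_response(grouped) if grouped else pd.DataFrame(
        columns=["concentration", "n", "mean_delta_cnp", "sd_delta_cnp", "sd_defined"])
    return AssayResult(steps=table, blank_stats=stats, dose_response=dr)
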