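"""Manifest-driven orchestration of the Raman and KPFM analysis chains.

A run manifest is a CSV with one row per incubation step:

    replicate_id, label, analyte, concentration_molar, input, kind

``kind`` is ``spectra_dir`` (a directory of two-column spectrum files with
the acquisition bias in their headers), ``dispersion_table`` (a 3-column
text file of V_G, ω_G, σ) or ``sp_map`` (a surface-potential grid written
by :func:`diracsense.kpfm.write_sp_map`). Each replicate needs exactly one
``baseline`` row. Results are emitted as CSV tables plus a JSON run
summary; per-step failures are recorded and skipped, and the run reports
whether any sensing step failed.
"""

from __future__ import annotations

import glob
import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assay import AssayStep, evaluate_assay
from .cnp import CNPFitResult, DispersionModel
from .gating import GatingParams
from .kpfm import delta_spd, read_sp_map, spd
from .spectra import DispersionCurve, build_dispersion, read_spectrum

__all__ = ["RunManifest", "run_raman_pipeline", "run_kpfm_pipeline"]

log = logging.getLogger("diracsense")

_RAMAN_KINDS = {"spectra_dir", "dispersion_table"}
_REQUIRED_COLUMNS = ["replicate_id", "label", "analyte", "concentration_molar",
                     "input", "kind"]


@dataclass
class RunManifest:
    """Validated table of per-step inputs."""

    table: pd.DataFrame
    root: str = "."

    @classmethod
    def read(cls, path) -> "RunManifest":
        df = pd.read_csv(path, dtype={"replicate_id": str})
        return cls(df, root=os.path.dirname(os.path.abspath(str(path))))

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"manifest is missing columns {missing}")
        for rep, group in self.table.groupby("replicate_id"):
            n_base = int((group["label"] == "baseline").sum())
            if n_base != 1:
                raise ValueError(
                    f"replicate {rep!r} has {n_base} baseline rows (need exactly 1)")
        kinds = set(self.table["kind"])
        if kinds & _RAMAN_KINDS and "sp_map" in kinds:
            raise ValueError("manifest mixes Raman and KPFM input kinds")

    def resolve(self, p: str) -> str:
        return p if os.path.isabs(p) else os.path.join(self.root, p)


def _fit_step_input(manifest: RunManifest, row, base: GatingParams) -> CNPFitResult:
    path = manifest.resolve(row["input"])
    if row["kind"] == "spectra_dir":
        files = sorted(glob.glob(os.path.join(path, "*.txt")))
        if not files:
            raise FileNotFoundError(f"no spectrum files in {path}")
        spectra = [read_spectrum(f) for f in files]
        curve = build_dispersion(spectra)
    elif row["kind"] == "dispersion_table":
        curve = DispersionCurve.from_table(np.loadtxt(path))
    else:
        raise ValueError(f"unknown Raman input kind {row['kind']!r}")
    return DispersionModel(curve, base=base).fit()


def run_raman_pipeline(manifest: RunManifest | pd.DataFrame, outdir: str,
                       base: GatingParams | None = None,
                       lod_override: float | None = None) -> dict:
    """Spectra → dispersion → CNP → assay metrics, with files written.

    Writes ``cnp_fits.csv`` (one row per step), ``assay_results.csv``
    (ΔCNP with OFF/ON calls), ``dose_response.csv`` and ``summary.json``
    under ``outdir``. ``lod_override`` classifies against a fixed platform
    LOD (mV) instead of the one estimated from this run's blanks. Returns
    the summary dict; ``summary["ok"]`` is False when any sensing step
    failed.
    """
    if not isinstance(manifest, RunManifest):
        manifest = RunManifest(manifest)
    if base is None:
        base = GatingParams()
    os.makedirs(outdir, exist_ok=True)

    fit_rows, steps, failures = [], [], []
    for _, row in manifest.table.iterrows():
        try:
            fit = _fit_step_input(manifest, row, base)
        except Exception as exc:  # recorded, not fatal, unless sensing
            log.error("step %s/%s failed: %s", row["replicate_id"], row["label"], exc)
            failures.append({"replicate_id": row["replicate_id"],
                             "label": row["label"], "error": str(exc)})
            continue
        fit_rows.append({
            "replicate_id": row["replicate_id"], "label": row["label"],
            "analyte": row["analyte"], "concentration_molar": row["concentration_molar"],
            "v_cnp_mV": fit.v_cnp * 1e3, "v_cnp_sd_mV": fit.v_cnp_sd * 1e3,
            "areal_capacitance_F_m2": fit.areal_capacitance,
            "total_capacitance_uF": fit.total_capacitance * 1e6,
            "reduced_chi2": fit.reduced_chi2, "rmse_cm1": fit.rmse,
            "converged": fit.converged, "extrapolated": fit.extrapolated,
        })
        steps.append(AssayStep(label=row["label"], fit=fit, analyte=row["analyte"],
                               concentration=float(row["concentration_molar"]),
                               replicate_id=str(row["replicate_id"])))

    pd.DataFrame(fit_rows).to_csv(os.path.join(outdir, "cnp_fits.csv"), index=False)
    result = evaluate_assay(steps, lod=lod_override)
    result.steps.to_csv(os.path.join(outdir, "assay_results.csv"), index=False)
    result.dose_response.to_csv(os.path.join(outdir, "dose_response.csv"), index=False)

    sensing_failed = any(f["label"] == "sensing" for f in failures)
    summary = {
        "ok": not sensing_failed,
        "n_steps": int(len(manifest.table)),
        "n_failed": len(failures),
        "failures": failures,
        "lod_mV": result.lod if lod_override is None else lod_override,
        "loi_mV": result.loi,
        "blank_mu_n_mV": result.blank_stats.mu_n,
        "blank_sigma_mV": result.blank_stats.sigma,
        "calls": result.steps[["replicate_id", "label", "concentration",
                               "delta_cnp_mV", "call"]].to_dict("records"),
    }
    with open(os.path.join(outdir, "summary.json"), "wt", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def run_kpfm_pipeline(manifest: RunManifest | pd.DataFrame, outdir: str) -> dict:
    """Surface-potential maps → SPD per step → ΔSPD table.

    Maps are zeroed on their reference region, the biolayer histogram is
    Gaussian-fitted, and every non-baseline step is differenced against
    its replicate's baseline SPD. Steps whose map fails (e.g. empty mask)
    are flagged and the run continues.
    """
    if not isinstance(manifest, RunManifest):
        manifest = RunManifest(manifest)
    os.makedirs(outdir, exist_ok=True)

    spd_rows, failures = [], []
    baselines: dict[str, object] = {}
    results: list[tuple[pd.Series, object]] = []
    for _, row in manifest.table.iterrows():
        if row["kind"] != "sp_map":
            raise ValueError(f"KPFM pipeline got input kind {row['kind']!r}")
        try:
            result = spd(read_sp_map(manifest.resolve(row["input"]), label=row["label"]))
        except Exception as exc:
            log.error("KPFM step %s/%s failed: %s", row["replicate_id"], row["label"], exc)
            failures.append({"replicate_id": row["replicate_id"],
                             "label": row["label"], "error": str(exc)})
            continue
        if row["label"] == "baseline":
            baselines[str(row["replicate_id"])] = result
        results.append((row, result))

    for row, result in results:
        if row["label"] == "baseline":
            continue
        rep = str(row["replicate_id"])
        if rep not in baselines:
            failures.append({"replicate_id": rep, "label": row["label"],
                             "error": "no baseline map for replicate"})
            continue
        shift = delta_spd(baselines[rep], result)
        spd_rows.append({
            "replicate_id": rep, "label": row["label"], "analyte": row["analyte"],
            "concentration_molar": row["concentration_molar"],
            "spd_mV": result.spd, "delta_spd_mV": shift.value, "sd_mV": shift.sd,
        })

    table = pd.DataFrame(spd_rows)
    table.to_csv(os.path.join(outdir, "delta_spd.csv"), index=False)
    summary = {"ok": len(failures) == 0, "n_steps": int(len(manifest.table)),
               "n_failed": len(failures), "failures": failures,
               "delta_spd": spd_rows}
    with open(os.path.join(outdir, "kpfm_summary.json"), "wt", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2)
    return summary
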