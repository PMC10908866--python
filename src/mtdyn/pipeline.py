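"""End-to-end pipeline driver and integrated per-residue report.

Stages run in a fixed order — classify, segment, quantify, CSP, binding
fits — each logged with its parameters and row counts; outputs are CSV and
JSON files ready for plotting.  Identical configuration and seeds give
byte-identical outputs.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import quantify
from .binding import fit_anisotropy, fit_itc, read_anisotropy, read_thermogram
from .csp import fit_titration_kd, profile_from_peaklists, salt_series, significance
from .editing import classify_residues, match_peaks, segment_profile
from .peaks import read_peak_list
from .quantify import helicity_deltas
from .reference import load_reference_library
from .sequence import parse_sequence
from .shifts import read_shift_table
from .spectrum import AxesSpec, RegionDefinition
from .synth import LINEWIDTHS, NoiseModel, rasterize

log = logging.getLogger("mtdyn")


class PipelineError(RuntimeError):
    pass


class PipelineConfig(BaseModel):
    """Round-trippable run configuration; all paths relative to fixture_dir."""

    fixture_dir: str
    output_dir: str
    tol_h: float = 0.05
    tol_c: float = 0.5
    alpha: float = 0.154
    min_run: int = 3
    min_len: int = 3
    seed: int = 0
    raster_baseline_sd: float = 0.02
    stages: list[str] = Field(
        default_factory=lambda: ["classify", "quantify", "csp", "fits"]
    )

    def validate_paths(self) -> None:
        root = Path(self.fixture_dir)
        required = [
            "sequence.txt", "solution_shifts.csv", "ssnmr_shifts.csv",
            "dipolar.peaks", "scalar.peaks", "titration.json",
            "itc_thermogram.csv", "anisotropy.csv",
            "trosy_free.peaks", "trosy_bound.peaks",
        ]
        missing = [p for p in required if not (root / p).exists()]
        if missing:
            raise PipelineError(f"config validation: missing inputs {missing}")


def _tight_region(table, residue: int, c_atom: str, h_atom: str,
                  channel: str) -> RegionDefinition:
    """Small box (+/- 3 linewidths) around one assigned peak position."""
    c = table.get(residue, c_atom)
    h = table.get(residue, h_atom)
    lw = LINEWIDTHS[channel]
    return RegionDefinition(
        f"ref_{residue}{c_atom}{h_atom}",
        (h - 3 * lw["H"], h + 3 * lw["H"]),
        (c - 3 * lw["C"], c + 3 * lw["C"]),
    )


# single-resonance reference peaks per channel: well-resolved side-chain /
# backbone resonances of residues known to sit in that dynamic class
SCALAR_REFS = [(86, "CG2", "HG2"), (158, "CB", "HB"), (159, "CD", "HD")]
DIPOLAR_REFS = [(122, "CA", "HA"), (103, "CB", "HB"), (142, "CG1", "HG1")]


def run_pipeline(config: PipelineConfig) -> dict:
    config.validate_paths()
    root = Path(config.fixture_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log.info("pipeline start: %s", config.model_dump())

    try:
        start_line, seq_line = (root / "sequence.txt").read_text().split()
        sequence = parse_sequence(seq_line, int(start_line))
        solution = read_shift_table(root / "solution_shifts.csv")
        ssnmr = read_shift_table(root / "ssnmr_shifts.csv")
        library = load_reference_library()
        dip_list = read_peak_list(root / "dipolar.peaks", dims=2,
                                  channel="dipolar")
        sca_list = read_peak_list(root / "scalar.peaks", dims=2,
                                  channel="scalar")

        # --- classify -----------------------------------------------------
        dip_match = match_peaks(dip_list, solution, library,
                                config.tol_h, config.tol_c)
        sca_match = match_peaks(sca_list, solution, library,
                                config.tol_h, config.tol_c)
        residues = [r.number for r in sequence]
        profile = classify_residues(dip_match, sca_match, residues=residues)
        segments = segment_profile(profile, min_run=config.min_run)
        log.info("classify: %d dipolar + %d scalar peaks, %d residues",
                 len(dip_list), len(sca_list), len(residues))
        rigidity_df = pd.DataFrame({
            "residue": residues,
            "residue_type": [sequence[r] for r in residues],
            "call": [profile.calls[r] for r in residues],
            "annotation": [profile.annotations.get(r, "") for r in residues],
            "dipolar_atoms": [";".join(sorted(profile.evidence[r]["dipolar"]))
                              for r in residues],
            "scalar_atoms": [";".join(sorted(profile.evidence[r]["scalar"]))
                             for r in residues],
        })
        _write_csv(rigidity_df, outdir / "rigidity.csv", written)
        _write_json(segments.as_dict(), outdir / "segments.json", written)

        # --- quantify -----------------------------------------------------
        noise = NoiseModel(seed=config.seed, baseline_sd=config.raster_baseline_sd)
        axes = AxesSpec()
        rasters = {"dipolar": rasterize(dip_list, axes, noise),
                   "scalar": rasterize(sca_list, axes, noise)}
        refs = {
            "scalar": [_tight_region(solution, *r, "scalar") for r in SCALAR_REFS],
            "dipolar": [_tight_region(solution, *r, "dipolar") for r in DIPOLAR_REFS],
        }
        seg_for = {
            "scalar": [s for s in (segments.n_flex, segments.c_flex) if s],
            "dipolar": [segments.rigid_core] if segments.rigid_core else [],
        }
        estimates = []
        for channel in ("scalar", "dipolar"):
            spec_r = rasters[channel]
            ref_integral = quantify.single_peak_reference(spec_r, refs[channel])
            for region in quantify.load_default_regions():
                res_type = region.name.split("_")[0]
                try:
                    integral, snr = quantify.integrate_region(spec_r, region)
                except Exception:
                    continue
                predicted = quantify.predicted_counts(
                    sequence, seg_for[channel], res_type)
                est = quantify.estimate_abundance(
                    integral, ref_integral, snr,
                    region_name=f"{channel}:{region.name}", predicted=predicted)
                estimates.append(est)
        _write_csv(quantify.abundance_table(estimates),
                   outdir / "abundance.csv", written)
        deltas = helicity_deltas(ssnmr, solution)
        _write_csv(pd.DataFrame([d.__dict__ for d in deltas]),
                   outdir / "helicity.csv", written)

        # --- csp ----------------------------------------------------------
        tmeta = json.loads((root / "titration.json").read_text())
        series = [read_peak_list(root / f, dims=2, experiment="NH-TROSY")
                  for f in tmeta["files"]]
        prof = profile_from_peaklists(series[0], series[-1], alpha=config.alpha)
        sig = significance(prof, min_len=config.min_len)
        csp_df = prof.df.copy()
        csp_df["significant"] = [
            bool(sig.flags.get(int(r), False)) for r in csp_df["residue"]
        ]
        _write_csv(csp_df, outdir / "csp.csv", written)
        _write_json(
            {"threshold_ppm": sig.threshold, "alpha": config.alpha,
             "stretches": [list(s) for s in sig.stretches]},
            outdir / "stretches.json", written)

        salt_report = None
        if (root / "salt.json").exists():
            smeta = json.loads((root / "salt.json").read_text())
            profs = {}
            for salt, (fname, bname) in smeta["files"].items():
                fpl = read_peak_list(root / fname, dims=2)
                bpl = read_peak_list(root / bname, dims=2)
                profs[float(salt)] = profile_from_peaklists(
                    fpl, bpl, alpha=config.alpha)
            salt_report = salt_series(profs, min_len=config.min_len)
            _write_json(salt_report, outdir / "salt_report.json", written)

        # --- fits ---------------------------------------------------------
        itc_res = fit_itc(read_thermogram(root / "itc_thermogram.csv"))
        fa_res = fit_anisotropy(read_anisotropy(root / "anisotropy.csv"))
        csp_fit = fit_titration_kd(series, tmeta["ligand_concs_uM"],
                                   tmeta["protein_conc_uM"], alpha=config.alpha)
        from .editing import intensity_ratio
        free_pl = read_peak_list(root / "trosy_free.peaks", dims=2)
        bound_pl = read_peak_list(root / "trosy_bound.peaks", dims=2)
        attenuation = intensity_ratio(free_pl, bound_pl)
        fits = {
            "itc": {"kd_uM": itc_res.kd_uM, "kd_se": itc_res.kd_se,
                    "n": itc_res.n, "n_se": itc_res.n_se,
                    "dh_kcal_mol": itc_res.dh_kcal_mol,
                    "flags": itc_res.flags},
            "anisotropy": {"kd_uM": fa_res.kd_uM, "kd_se": fa_res.kd_se,
                           "r_free": fa_res.r_free, "r_bound": fa_res.r_bound,
                           "flags": fa_res.flags},
            "csp_titration": {"kd_uM": csp_fit.kd_uM, "kd_se": csp_fit.kd_se,
                              "flags": csp_fit.flags},
            "trosy_attenuation": attenuation,
        }
        _write_json(fits, outdir / "fits.json", written)

        # --- integrated per-residue summary -------------------------------
        helical_types = {
            d.residue_type for d in deltas if d.atom == "CA" and d.helical_consistent
        }
        sig_set = {r for r, f in sig.flags.items() if f}

        def seg_of(r: int) -> str:
            for name, rng in segments.as_dict().items():
                if rng and rng[0] <= r <= rng[1]:
                    return name
            return ""

        summary = pd.DataFrame({
            "residue": residues,
            "residue_type": [sequence[r] for r in residues],
            "rigidity": [profile.calls[r] for r in residues],
            "segment": [seg_of(r) for r in residues],
            "csp_significant": [r in sig_set for r in residues],
            "helical_consistent_type": [sequence[r] in helical_types
                                        for r in residues],
        })
        _write_csv(summary, outdir / "residue_summary.csv", written)
    except Exception:
        for p in written:  # no partial bundles
            p.unlink(missing_ok=True)
        raise
    log.info("pipeline done: %d output files", len(written))
    return {"outputs": [str(p) for p in written], "fits": fits,
            "segments": segments.as_dict(),
            "stretches": [list(s) for s in sig.stretches]}


def _write_csv(df: pd.DataFrame, path: Path, written: list[Path]) -> None:
    df.to_csv(path, index=False, float_format="%.6g")
    written.append(path)


def _write_json(obj, path: Path, written: list[Path]) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True,
                               default=_json_default) + "\n")
    written.append(path)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(type(o))
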