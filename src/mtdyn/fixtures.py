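"""Study-condition synthetic fixture bundle.

:func:`make_fixtures` writes, under one directory, every input the
pipeline consumes, generated with known ground truth that mirrors the
MTBD study conditions: flexible termini around a rigid helical core,
CSP hot-spots at 82-88 and 141-146, a micromolar ITC isotherm at the
documented injection schedule, a ~91 uM anisotropy curve, an
electrostatically screened salt series and a 90% TROSY attenuation pair.
Identical seeds give bit-identical directories.
"""
from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .binding import ITCSchedule, write_anisotropy, write_thermogram
from .reference import load_reference_library
from .sequence import load_mtbd_sequence
from .shifts import ChemicalShiftTable
from .synth import (
    HELICAL_OFFSET,
    BindingGroundTruth,
    NoiseModel,
    RigidityGroundTruth,
    generate_anisotropy_series,
    generate_attenuation_pair,
    generate_editing_peaklists,
    generate_itc_thermogram,
    generate_shift_table,
    generate_titration_series,
    nh_table,
)

# ground-truth study conditions (see docs/methods.md for rationale)
FLEXIBLE_SEGMENTS = [(59, 69), (149, 170)]
BOTH_RESIDUES = [(70, 70), (148, 148)]
MOBILE_SIDECHAIN = {(86, "CG1"): "flexible", (86, "CG2"): "flexible",
                    (86, "CD1"): "flexible"}
HELICAL_SPAN = (70, 148)

CSP_MAIN = {r: (0.12, 0.60) for r in list(range(82, 89)) + list(range(141, 147))}
CSP_MINOR = {65: (0.04, 0.20), 75: (0.04, 0.20), 106: (0.04, 0.20),
             122: (0.04, 0.20), 150: (0.04, 0.20)}
CSP_DDMAX = {**CSP_MAIN, **CSP_MINOR}

TITRATION_CONCS_UM = [0.0, 20.0, 40.0, 80.0, 160.0, 320.0, 640.0, 800.0]
PROTEIN_CONC_UM = 80.0
SALTS_MM = [150.0, 300.0, 500.0]
SALT_LIGAND_UM = 800.0  # ten-fold peptide over protein

ITC_TRUTH = BindingGroundTruth(kd_uM=0.94, n=0.51, dh_kcal_mol=-8.0)
CTT_TRUTH = BindingGroundTruth(kd_uM=91.3, r_free=0.05, r_bound=0.20)
CTT_SALT_TRUTH = BindingGroundTruth(kd_uM=91.3, salt_decay_per_mM=0.006)
ANISO_PROBE_UM = 1.0
ANISO_TITRANT_UM = [200.0, 100.0, 50.0, 25.0, 12.5, 6.25, 3.125,
                    1.5625, 0.78125, 0.390625, 0.0]
TROSY_ATTENUATION = 0.90


def ssnmr_noise(seed: int) -> NoiseModel:
    return NoiseModel(seed=seed, jitter_h=0.05 / 3, jitter_c=0.5 / 3,
                      intensity_rel_sd=0.05, baseline_sd=0.02)


def solution_noise(seed: int) -> NoiseModel:
    return NoiseModel(seed=seed, jitter_h=0.003, jitter_n=0.02,
                      intensity_rel_sd=0.03)


def itc_noise(seed: int) -> NoiseModel:
    return NoiseModel(seed=seed, baseline_sd=0.2)  # uJ per injection


def rigidity_truth() -> RigidityGroundTruth:
    truth = RigidityGroundTruth.from_segments(
        load_mtbd_sequence(), flexible=FLEXIBLE_SEGMENTS, both=BOTH_RESIDUES
    )
    truth.atom_overrides.update(MOBILE_SIDECHAIN)
    return truth


def make_fixtures(seed: int, outdir: str | Path, noiseless: bool = False) -> Path:
    """Write the full synthetic dataset; returns the directory path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sequence = load_mtbd_sequence()
    library = load_reference_library()

    (out / "sequence.txt").write_text(
        f"{sequence.start}\n{sequence.one_letter}\n"
    )

    solution = generate_shift_table(sequence, library, seed=seed)
    solution.write(out / "solution_shifts.csv")

    # solid-state shifts as read from the dipolar 3D: helical secondary
    # shifts on the rigid span
    ss_df = solution.df.copy()
    in_span = ss_df["residue_number"].between(*HELICAL_SPAN)
    for atom, off in HELICAL_OFFSET.items():
        sel = in_span & (ss_df["atom_name"] == atom)
        ss_df.loc[sel, "shift"] = (ss_df.loc[sel, "shift"] + off).round(4)
    ChemicalShiftTable(ss_df).write(out / "ssnmr_shifts.csv")

    noise_ch = ssnmr_noise(seed).silent() if noiseless else ssnmr_noise(seed)
    dip, sca = generate_editing_peaklists(sequence, solution, rigidity_truth(),
                                          noise_ch)
    dip.write(out / "dipolar.peaks")
    sca.write(out / "scalar.peaks")

    noise_nh = solution_noise(seed).silent() if noiseless else solution_noise(seed)
    series = generate_titration_series(
        nh_table(solution), CSP_DDMAX, TITRATION_CONCS_UM, PROTEIN_CONC_UM,
        CTT_TRUTH, noise_nh,
    )
    tdir = out / "titration"
    tdir.mkdir(exist_ok=True)
    for i, (conc, pl) in enumerate(zip(TITRATION_CONCS_UM, series)):
        pl.write(tdir / f"titr_{i:02d}.peaks")
    (out / "titration.json").write_text(json.dumps({
        "ligand_concs_uM": TITRATION_CONCS_UM,
        "protein_conc_uM": PROTEIN_CONC_UM,
        "files": [f"titration/titr_{i:02d}.peaks"
                  for i in range(len(TITRATION_CONCS_UM))],
    }, indent=1))

    sdir = out / "salt"
    sdir.mkdir(exist_ok=True)
    salt_files = {}
    for salt in SALTS_MM:
        noise_s = solution_noise(seed + int(salt))
        if noiseless:
            noise_s = noise_s.silent()
        pair = generate_titration_series(
            nh_table(solution), CSP_DDMAX, [0.0, SALT_LIGAND_UM],
            PROTEIN_CONC_UM, CTT_SALT_TRUTH, noise_s, salt_mM=salt,
        )
        free_name = f"salt/free_{int(salt)}mM.peaks"
        bound_name = f"salt/bound_{int(salt)}mM.peaks"
        pair[0].write(out / free_name)
        pair[1].write(out / bound_name)
        salt_files[str(int(salt))] = [free_name, bound_name]
    (out / "salt.json").write_text(json.dumps(
        {"ligand_uM": SALT_LIGAND_UM, "files": salt_files}, indent=1))

    noise_itc = itc_noise(seed).silent() if noiseless else itc_noise(seed)
    thermo = generate_itc_thermogram(ITCSchedule(), ITC_TRUTH, noise_itc)
    write_thermogram(thermo, out / "itc_thermogram.csv")

    noise_fa = NoiseModel(seed=seed + 1)
    aniso = generate_anisotropy_series(
        ANISO_PROBE_UM, sorted(ANISO_TITRANT_UM), CTT_TRUTH, noise_fa,
        anisotropy_sd=0.0 if noiseless else 0.003,
    )
    write_anisotropy(aniso, out / "anisotropy.csv")

    free, bound = generate_attenuation_pair(
        nh_table(solution), TROSY_ATTENUATION, NoiseModel(seed=seed)
    )
    free.write(out / "trosy_free.peaks")
    bound.write(out / "trosy_bound.peaks")

    (out / "ground_truth.json").write_text(json.dumps({
        "seed": seed,
        "flexible_segments": FLEXIBLE_SEGMENTS,
        "both_residues": BOTH_RESIDUES,
        "helical_span": list(HELICAL_SPAN),
        "csp_ddmax": {str(k): v for k, v in CSP_DDMAX.items()},
        "itc": {"kd_uM": ITC_TRUTH.kd_uM, "n": ITC_TRUTH.n,
                "dh_kcal_mol": ITC_TRUTH.dh_kcal_mol},
        "ctt": {"kd_uM": CTT_TRUTH.kd_uM, "r_free": CTT_TRUTH.r_free,
                "r_bound": CTT_TRUTH.r_bound},
        "trosy_attenuation": TROSY_ATTENUATION,
    }, indent=1))
    return out
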