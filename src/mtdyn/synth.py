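"""Synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here:
dynamics-edited CH peak lists (dipolar = rigid filter, scalar = mobile
filter), rastered 2D spectra, NH titration series under fast exchange,
Wiseman ITC thermograms, quadratic anisotropy curves, and free/bound
TROSY attenuation pairs.  All randomness flows through an explicit seed
carried by :class:`NoiseModel`; the same seed yields bit-identical output.

Default linewidths follow the line-broadening applied to the underlying
experiments (120 Hz dipolar / 30 Hz scalar at 700 MHz): 1H FWHM 0.17 /
0.05 ppm, 13C FWHM 0.5 / 0.2 ppm.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .binding import (
    AnisotropySeries,
    BindingError,
    ITCSchedule,
    ITCThermogram,
    anisotropy_model,
    bound_fraction,
    wiseman_heats,
)
from .peaks import Peak, PeakList, ch_label, nh_label
from .reference import ReferenceShiftLibrary
from .sequence import ProteinSequence
from .shifts import ChemicalShiftTable
from .spectrum import AxesSpec, Spectrum2D, render_peaks

RIGIDITY_STATES = ("rigid", "flexible", "both", "invisible")

# mean helical secondary shifts added to rigid-helix residues on request
HELICAL_OFFSET = {"CA": +2.6, "CB": -0.4}

LINEWIDTHS = {
    "dipolar": {"H": 0.17, "C": 0.50},
    "scalar": {"H": 0.05, "C": 0.20},
}


class GenerationError(ValueError):
    pass


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian, per-point-independent noise with a mandatory seed."""

    seed: int
    jitter_h: float = 0.0       # ppm sd on 1H positions
    jitter_c: float = 0.0       # ppm sd on 13C positions
    jitter_n: float = 0.0       # ppm sd on 15N positions
    intensity_rel_sd: float = 0.0
    baseline_sd: float = 0.0    # raster noise, intensity units

    def __post_init__(self):
        if min(self.jitter_h, self.jitter_c, self.jitter_n,
               self.intensity_rel_sd, self.baseline_sd) < 0:
            raise GenerationError("noise sds must be >= 0")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])

    def silent(self) -> "NoiseModel":
        return NoiseModel(seed=self.seed)


DEFAULT_NOISE = NoiseModel(
    seed=0, jitter_h=0.05 / 3, jitter_c=0.5 / 3, jitter_n=0.1,
    intensity_rel_sd=0.05, baseline_sd=0.02,
)


@dataclass
class RigidityGroundTruth:
    """Per-residue dynamic state, with optional per-atom overrides.

    ``states`` maps residue number -> state; ``atom_overrides`` maps
    (residue number, carbon atom name) -> state, e.g. a rigid backbone
    with a flexible methyl side chain.
    """

    states: dict[int, str]
    atom_overrides: dict[tuple[int, str], str] = field(default_factory=dict)

    def __post_init__(self):
        for state in list(self.states.values()) + list(self.atom_overrides.values()):
            if state not in RIGIDITY_STATES:
                raise GenerationError(f"unknown rigidity state {state!r}")

    def state_of(self, residue: int, c_atom: str | None = None) -> str:
        if c_atom is not None and (residue, c_atom) in self.atom_overrides:
            return self.atom_overrides[(residue, c_atom)]
        return self.states[residue]

    @classmethod
    def from_segments(
        cls,
        sequence: ProteinSequence,
        flexible: list[tuple[int, int]],
        invisible: list[tuple[int, int]] = (),
        both: list[tuple[int, int]] = (),
    ) -> "RigidityGroundTruth":
        states = {r.number: "rigid" for r in sequence}
        for lo, hi in flexible:
            for n in range(lo, hi + 1):
                states[n] = "flexible"
        for lo, hi in both:
            for n in range(lo, hi + 1):
                states[n] = "both"
        for lo, hi in invisible:
            for n in range(lo, hi + 1):
                states[n] = "invisible"
        return cls(states)


@dataclass(frozen=True)
class BindingGroundTruth:
    kd_uM: float
    n: float = 1.0                      # ITC stoichiometry
    dh_kcal_mol: float = -8.0           # ITC enthalpy
    ddmax_h: float = 0.10               # default per-residue CSP amplitude, 1H ppm
    ddmax_n: float = 0.50               # 15N ppm
    r_free: float = 0.05
    r_bound: float = 0.20
    salt_decay_per_mM: float = 0.0      # screening: ddmax * exp(-kappa * salt)

    def __post_init__(self):
        if self.kd_uM <= 0 or self.n <= 0:
            raise BindingError("K_D and n must be positive")
        if self.r_free >= self.r_bound:
            raise BindingError("degenerate anisotropy truth: r_free >= r_bound")


# ---------------------------------------------------------------------------
# assignment-table synthesis
# ---------------------------------------------------------------------------

def generate_shift_table(
    sequence: ProteinSequence,
    library: ReferenceShiftLibrary,
    seed: int = 0,
    scatter: float = 1.0,
    helical_span: tuple[int, int] | None = None,
) -> ChemicalShiftTable:
    """Draw a full assignment table around database-average positions.

    Each residue receives every atom the ``bmrb_average`` source lists
    for its type, drawn from a Gaussian with ``scatter`` times the
    database sd (seeded): at the default scatter of 1 each shift is a
    draw from the atom's database distribution itself, reproducing the
    realistic dispersion (and crowding) of an assigned protein.  Residues
    inside ``helical_span`` get the mean helical secondary shift added to
    CA/CB.
    """
    rng = np.random.default_rng([seed, 101])
    rows = []
    for res in sequence:
        for atom in library.atoms_for(res.code, "bmrb_average"):
            stat = library.lookup(res.code, atom, "bmrb_average")
            shift = stat.mean + rng.normal(0.0, scatter * stat.sd)
            if (
                helical_span is not None
                and helical_span[0] <= res.number <= helical_span[1]
                and atom in HELICAL_OFFSET
            ):
                shift += HELICAL_OFFSET[atom]
            rows.append((res.number, res.code, atom, round(shift, 4)))
    return ChemicalShiftTable(
        pd.DataFrame(rows, columns=["residue_number", "residue_type",
                                    "atom_name", "shift"])
    )


def ch_pairs(table: ChemicalShiftTable, residue: int) -> list[tuple[str, str]]:
    """Carbon-proton pairs available for a residue: C<suffix> with H<suffix>."""
    atoms = set(table.atoms_of(residue))
    pairs = []
    for atom in sorted(atoms):
        if atom.startswith("C") and len(atom) > 1:
            h_atom = "H" + atom[1:]
            if h_atom in atoms:
                pairs.append((atom, h_atom))
    return pairs


# ---------------------------------------------------------------------------
# dynamics-edited peak lists
# ---------------------------------------------------------------------------

def generate_editing_peaklists(
    sequence: ProteinSequence,
    shift_table: ChemicalShiftTable,
    ground_truth: RigidityGroundTruth,
    noise: NoiseModel,
    linewidths: dict | None = None,
) -> tuple[PeakList, PeakList]:
    """Dipolar (rigid-filtered) and scalar (mobile-filtered) 2D CH lists.

    Residues emit every CH pair present in the shift table into the
    channel(s) their state selects: flexible -> scalar only, rigid ->
    dipolar only, both -> both, invisible -> neither.  Positions are the
    assigned shifts plus seeded jitter; coordinates are (13C, 1H) in
    acquisition order.
    """
    lw = linewidths or LINEWIDTHS
    rngs = {"dipolar": noise.rng(1), "scalar": noise.rng(2)}
    lists = {ch: [] for ch in ("dipolar", "scalar")}
    for res in sequence:
        if res.number not in ground_truth.states:
            raise GenerationError(f"no ground-truth state for residue {res.number}")
        pairs = ch_pairs(shift_table, res.number)
        if not pairs and ground_truth.state_of(res.number) != "invisible":
            raise GenerationError(
                f"residue {res.number} has no CH shifts in the assignment table"
            )
        for c_atom, h_atom in pairs:
            state = ground_truth.state_of(res.number, c_atom)
            channels = {
                "rigid": ("dipolar",),
                "flexible": ("scalar",),
                "both": ("dipolar", "scalar"),
                "invisible": (),
            }[state]
            for ch in channels:
                rng = rngs[ch]
                c_ppm = shift_table.get(res.number, c_atom)
                h_ppm = shift_table.get(res.number, h_atom)
                pos = (
                    c_ppm + rng.normal(0.0, noise.jitter_c),
                    h_ppm + rng.normal(0.0, noise.jitter_h),
                )
                inten = max(1.0 + rng.normal(0.0, noise.intensity_rel_sd), 0.0)
                lists[ch].append(
                    Peak(
                        position=(round(pos[0], 4), round(pos[1], 4)),
                        intensity=inten,
                        linewidth=(lw[ch]["C"], lw[ch]["H"]),
                        label=ch_label(res.code, res.number, c_atom, h_atom),
                    )
                )
    dip = PeakList(2, lists["dipolar"], channel="dipolar", experiment="CH-2D")
    sca = PeakList(2, lists["scalar"], channel="scalar", experiment="CH-2D")
    return dip, sca


def rasterize(
    peaklist: PeakList,
    axes: AxesSpec,
    noise: NoiseModel,
) -> Spectrum2D:
    """Render a 2D CH peak list onto a regular grid with Gaussian lineshapes.

    The analytic integral of each rendered peak equals its intensity;
    baseline Gaussian noise of sd ``noise.baseline_sd`` is added per point.
    """
    if peaklist.dims != 2:
        raise GenerationError("rasterize expects a 2D peak list")
    h_grid, c_grid = axes.grids()
    positions, intens, fh, fc = [], [], [], []
    for p in peaklist.peaks:
        c_ppm, h_ppm = p.position
        if not (h_grid[0] <= h_ppm <= h_grid[-1] and c_grid[0] <= c_ppm <= c_grid[-1]):
            raise GenerationError(
                f"peak {p.label!r} at ({c_ppm}, {h_ppm}) outside axes"
            )
        lw = p.linewidth or (LINEWIDTHS["dipolar"]["C"], LINEWIDTHS["dipolar"]["H"])
        positions.append((h_ppm, c_ppm))
        intens.append(p.intensity)
        fc.append(lw[0])
        fh.append(lw[1])
    data = render_peaks(
        axes,
        np.asarray(positions).reshape(-1, 2),
        np.asarray(intens),
        np.asarray(fh),
        np.asarray(fc),
    )
    if noise.baseline_sd > 0:
        data = data + noise.rng(3).normal(0.0, noise.baseline_sd, size=data.shape)
    return Spectrum2D(h_grid, c_grid, data, noise_floor=noise.baseline_sd,
                      meta={"channel": peaklist.channel})


def generate_population_spectrum(
    ratio: float,
    noise: NoiseModel,
    axes: AxesSpec | None = None,
):
    """Dipolar CA-HA spectrum of two conformational populations.

    Renders a helical CA-HA cluster (downfield 13C, upfield 1H) and a
    beta-strand CA-HA cluster whose summed intensities stand in the given
    population ratio, plus one isolated unit-intensity reference peak.
    Returns ``(spectrum, helical_region, strand_region, reference_region)``
    sized so each region captures its cluster to well under 1%.
    """
    from .spectrum import RegionDefinition

    if ratio <= 0:
        raise GenerationError("population ratio must be positive")
    axes = axes or AxesSpec()
    lw = (LINEWIDTHS["dipolar"]["C"], LINEWIDTHS["dipolar"]["H"])
    helical = [
        Peak((55.5 + 0.2 * i, 3.95 + 0.03 * i), ratio / 5.0, lw)
        for i in range(5)
    ]
    strand = [Peak((51.0, 5.20), 0.5, lw), Peak((51.4, 5.35), 0.5, lw)]
    reference = [Peak((20.0, 1.30), 1.0, lw)]
    spectrum = rasterize(PeakList(2, helical + strand + reference,
                                  channel="dipolar"), axes, noise)
    return (
        spectrum,
        RegionDefinition("helical_CAHA", (3.30, 4.65), (54.0, 58.0)),
        RegionDefinition("strand_CAHA", (4.75, 5.85), (49.0, 53.0)),
        RegionDefinition("reference", (0.70, 1.90), (18.0, 22.0)),
    )


# ---------------------------------------------------------------------------
# NH titrations (fast exchange)
# ---------------------------------------------------------------------------

def nh_table(shift_table: ChemicalShiftTable) -> ChemicalShiftTable:
    return shift_table.subset(["N", "H"])


def generate_titration_series(
    shift_table: ChemicalShiftTable,
    ddmax: dict[int, tuple[float, float]],
    ligand_concs_uM: list[float],
    protein_conc_uM: float,
    truth: BindingGroundTruth,
    noise: NoiseModel,
    salt_mM: float = 150.0,
    linewidth_h: float = 0.02,
    linewidth_n: float = 0.15,
) -> list[PeakList]:
    """NH peak lists across a ligand titration under fast exchange.

    Observed shift = free shift + ddmax * (fraction of protein bound),
    the bound fraction from the exact mass-balance quadratic.  ``ddmax``
    maps residue number -> (ddmax_H, ddmax_N) in ppm; residues absent
    from the map do not move.  An optional electrostatic-screening decay
    scales every ddmax by ``exp(-kappa * salt)``.
    """
    concs = list(ligand_concs_uM)
    if any(c < 0 for c in concs):
        raise GenerationError("negative ligand concentration")
    if concs != sorted(concs) or (concs and concs[0] != 0):
        raise GenerationError("ligand concentrations must be ascending from 0")
    screen = np.exp(-truth.salt_decay_per_mM * salt_mM)
    rng = noise.rng(4)
    out = []
    for conc in concs:
        fb_protein = bound_fraction(protein_conc_uM, conc, truth.kd_uM)
        peaks = []
        for res_num in shift_table.residues():
            h0 = shift_table.get(res_num, "H")
            n0 = shift_table.get(res_num, "N")
            if h0 is None or n0 is None:
                continue  # e.g. prolines: no amide proton
            dh, dn = ddmax.get(res_num, (0.0, 0.0))
            pos = (
                h0 + dh * screen * fb_protein + rng.normal(0.0, noise.jitter_h),
                n0 + dn * screen * fb_protein + rng.normal(0.0, noise.jitter_n),
            )
            inten = max(1.0 + rng.normal(0.0, noise.intensity_rel_sd), 0.0)
            peaks.append(
                Peak(
                    position=(round(pos[0], 4), round(pos[1], 4)),
                    intensity=inten,
                    linewidth=(linewidth_h, linewidth_n),
                    label=nh_label(shift_table.residue_type(res_num), res_num),
                )
            )
        out.append(
            PeakList(2, peaks, channel="none", experiment="NH-TROSY",
                     condition={"ligand_uM": conc, "salt_mM": salt_mM})
        )
    return out


# ---------------------------------------------------------------------------
# calorimetry / anisotropy / attenuation
# ---------------------------------------------------------------------------

def generate_itc_thermogram(
    schedule: ITCSchedule,
    truth: BindingGroundTruth,
    noise: NoiseModel,
    dilution_offset_uJ: float = 0.0,
    corrupt_first: bool = False,
) -> ITCThermogram:
    """Wiseman 1:1 heats plus seeded Gaussian noise.

    ``noise.baseline_sd`` is interpreted as an absolute per-injection heat
    noise in uJ.  ``corrupt_first`` shrinks the first injection's heat, as
    syringe-tip diffusion does in practice, to exercise first-injection
    exclusion in the fitter."""
    heats = wiseman_heats(schedule, truth.kd_uM, truth.n, truth.dh_kcal_mol,
                          dilution_offset_uJ)
    rng = noise.rng(5)
    if noise.baseline_sd > 0:
        heats = heats + rng.normal(0.0, noise.baseline_sd, size=heats.shape)
    if corrupt_first:
        heats = heats.copy()
        heats[0] *= rng.uniform(0.2, 0.6)
    return ITCThermogram(schedule, heats,
                         meta={"truth_kd_uM": truth.kd_uM, "truth_n": truth.n,
                               "truth_dh": truth.dh_kcal_mol})


def generate_anisotropy_series(
    probe_conc_uM: float,
    titrant_concs_uM: list[float],
    truth: BindingGroundTruth,
    noise: NoiseModel,
    anisotropy_sd: float = 0.0,
) -> AnisotropySeries:
    if probe_conc_uM <= 0:
        raise GenerationError("probe concentration must be positive")
    p = np.asarray(titrant_concs_uM, dtype=float)
    r = anisotropy_model(p, probe_conc_uM, truth.kd_uM, truth.r_free, truth.r_bound)
    if anisotropy_sd > 0:
        r = r + noise.rng(6).normal(0.0, anisotropy_sd, size=r.shape)
    return AnisotropySeries(probe_conc_uM, p, r,
                            meta={"truth_kd_uM": truth.kd_uM})


def generate_attenuation_pair(
    shift_table: ChemicalShiftTable,
    attenuation_fraction: float,
    noise: NoiseModel,
) -> tuple[PeakList, PeakList]:
    """Free and bound NH-TROSY lists; bound intensity = free * (1 - f)."""
    if not 0.0 <= attenuation_fraction <= 1.0:
        raise GenerationError("attenuation fraction must lie in [0, 1]")
    rng = noise.rng(7)
    free_peaks, bound_peaks = [], []
    for res_num in shift_table.residues():
        h0 = shift_table.get(res_num, "H")
        n0 = shift_table.get(res_num, "N")
        if h0 is None or n0 is None:
            continue
        label = nh_label(shift_table.residue_type(res_num), res_num)
        inten = max(1.0 + rng.normal(0.0, noise.intensity_rel_sd), 0.0)
        pos = (round(h0, 4), round(n0, 4))
        free_peaks.append(Peak(pos, inten, (0.02, 0.15), label))
        bound_inten = inten * (1.0 - attenuation_fraction)
        if noise.intensity_rel_sd > 0:
            bound_inten = max(
                bound_inten * (1.0 + rng.normal(0.0, noise.intensity_rel_sd)), 0.0
            )
        bound_peaks.append(Peak(pos, bound_inten, (0.02, 0.15), label))
    free = PeakList(2, free_peaks, experiment="NH-TROSY", condition={"state": "free"})
    bound = PeakList(2, bound_peaks, experiment="NH-TROSY",
                     condition={"state": "bound"})
    return free, bound
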