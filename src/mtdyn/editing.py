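"""Rigid/flexible residue mapping from dynamics-edited spectra.

Dipolar (cross-polarization) transfers survive only at rigid sites and
scalar (J-based) transfers only at mobile ones, so overlaying the two
edited spectra against an assignment table classifies every residue as
rigid, flexible, both, or unobserved.  The profile is then segmented into
an N-terminal flexible arm, a rigid core and a C-terminal flexible arm.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .peaks import Peak, PeakList
from .reference import ReferenceShiftLibrary
from .sequence import ProteinSequence
from .shifts import ChemicalShiftTable
from .synth import ch_pairs

BACKBONE_ATOMS = frozenset({"CA", "HA", "CB", "HB"})


@dataclass(frozen=True)
class Match:
    peak_index: int
    residue_number: int
    atoms: tuple[str, ...]
    deviation: tuple[float, ...]  # ppm per dimension, observed - target
    d_norm: float                 # max(|dev_i| / tol_i)
    source: str                   # "assignment" or "bmrb_average"
    ambiguous: bool = False       # a competing target explains the peak
                                  # nearly as well (gap < margin)


@dataclass
class MatchSet:
    matches: list[Match]
    unmatched: list[int]          # peak indices
    tol_h: float
    tol_c: float
    peaklist: PeakList

    def residues(self) -> set[int]:
        return {m.residue_number for m in self.matches}

    def atoms_by_residue(self, unambiguous_only: bool = False
                         ) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for m in self.matches:
            if unambiguous_only and m.ambiguous:
                continue
            out.setdefault(m.residue_number, set()).update(m.atoms)
        return out


def _targets_ch(table: ChemicalShiftTable):
    rows = []
    for res_num in table.residues():
        for c_atom, h_atom in ch_pairs(table, res_num):
            rows.append(
                (res_num, (c_atom, h_atom),
                 table.get(res_num, c_atom), table.get(res_num, h_atom),
                 "assignment")
            )
    return rows


def match_peaks(
    peaklist: PeakList,
    shift_table: ChemicalShiftTable,
    reference_library: ReferenceShiftLibrary | None = None,
    tol_h: float = 0.05,
    tol_c: float = 0.5,
    ambiguity_margin: float = 0.3,
) -> MatchSet:
    """Greedy nearest-target matching of CH peaks against the assignments.

    Peak coordinates are (13C, 1H).  A peak matches the target minimising
    the normalised distance ``d = max(|dC|/tol_c, |dH|/tol_h)`` provided
    d <= 1; ties break on smaller d, then on lower residue number.
    Assignment-table targets take priority over database-average fallbacks
    (used only for residue types with no table entry).  Each peak matches
    at most once; targets may absorb several overlapping peaks.

    A match is flagged ambiguous when a target of another residue explains
    the peak nearly as well (second-best d within ``ambiguity_margin`` of
    the best): in crowded regions such peaks cannot safely be attributed
    to one residue and are kept as secondary evidence only.
    """
    if tol_h <= 0 or tol_c <= 0:
        raise ValueError("tolerances must be positive")
    targets = _targets_ch(shift_table)
    if reference_library is not None:
        covered_types = set(shift_table.df["residue_type"])
        for res_type in sorted(set("ACDEFGHIKLMNPQRSTVWY") - covered_types):
            for atom in reference_library.atoms_for(res_type, "bmrb_average"):
                if atom.startswith("C") and reference_library.has(
                    res_type, "H" + atom[1:], "bmrb_average"
                ):
                    c = reference_library.lookup(res_type, atom).mean
                    h = reference_library.lookup(res_type, "H" + atom[1:]).mean
                    targets.append((-1, (atom, "H" + atom[1:]), c, h,
                                    "bmrb_average"))
    matches: list[Match] = []
    unmatched: list[int] = []
    if not targets:
        return MatchSet([], list(range(len(peaklist.peaks))), tol_h, tol_c, peaklist)
    t_res = np.array([t[0] for t in targets])
    t_c = np.array([t[2] for t in targets])
    t_h = np.array([t[3] for t in targets])
    t_prio = np.array([0 if t[4] == "assignment" else 1 for t in targets])
    for i, peak in enumerate(peaklist.peaks):
        c_obs, h_obs = peak.position
        d = np.maximum(np.abs(c_obs - t_c) / tol_c, np.abs(h_obs - t_h) / tol_h)
        ok = d <= 1.0
        if not ok.any():
            unmatched.append(i)
            continue
        # priority: assignment targets first, then smallest d, then residue
        order = np.lexsort((t_res, d, t_prio))
        best = order[np.argmax(ok[order])]
        if not ok[best]:
            unmatched.append(i)
            continue
        res_num, atoms, c_t, h_t, source = targets[best]
        rival = d[(t_res != res_num)]
        gap = float(rival.min() - d[best]) if rival.size else float("inf")
        matches.append(
            Match(i, res_num, atoms, (c_obs - c_t, h_obs - h_t),
                  float(d[best]), source, ambiguous=gap < ambiguity_margin)
        )
    return MatchSet(matches, unmatched, tol_h, tol_c, peaklist)


@dataclass
class RigidityProfile:
    """Per-residue call with supporting atom-level evidence."""

    calls: dict[int, str]                       # rigid|flexible|both|unobserved
    evidence: dict[int, dict[str, set[str]]]    # residue -> channel -> atoms
    annotations: dict[int, str] = field(default_factory=dict)

    def residues(self) -> list[int]:
        return sorted(self.calls)


def classify_residues(
    dipolar: MatchSet,
    scalar: MatchSet,
    residues: list[int] | None = None,
    backbone_atoms: frozenset[str] = BACKBONE_ATOMS,
) -> RigidityProfile:
    """Combine dipolar and scalar match evidence into per-residue calls.

    Unambiguously attributed backbone atoms (CA/HA, CB/HB by default) are
    the primary evidence: the residue call is flexible / rigid / both
    according to which channel(s) carry such matches.  Side-chain-only or
    ambiguous evidence in a channel never flips the call on its own; it
    is recorded as an annotation (e.g. "rigid backbone, mobile side
    chain").  Residues with side-chain evidence only fall back to a
    side-chain-based call, annotated as such; residues with no matches at
    all are unobserved.
    """
    dip = dipolar.atoms_by_residue()
    sca = scalar.atoms_by_residue()
    dip_un = dipolar.atoms_by_residue(unambiguous_only=True)
    sca_un = scalar.atoms_by_residue(unambiguous_only=True)
    if residues is None:
        residues = sorted(set(dip) | set(sca))
    calls, evidence, notes = {}, {}, {}
    for res in residues:
        if res < 0:
            continue  # type-level database matches carry no residue call
        d_atoms = dip.get(res, set())
        s_atoms = sca.get(res, set())
        evidence[res] = {"dipolar": d_atoms, "scalar": s_atoms}
        d_bb = dip_un.get(res, set()) & backbone_atoms
        s_bb = sca_un.get(res, set()) & backbone_atoms
        if d_bb and s_bb:
            calls[res] = "both"
        elif d_bb:
            calls[res] = "rigid"
            if s_atoms:
                notes[res] = "rigid backbone, mobile side chain"
        elif s_bb:
            calls[res] = "flexible"
            if d_atoms:
                notes[res] = "flexible backbone, rigid side chain"
        elif d_atoms and s_atoms:
            calls[res] = "both"
            notes[res] = "side-chain evidence only"
        elif d_atoms:
            calls[res] = "rigid"
            notes[res] = "side-chain evidence only"
        elif s_atoms:
            calls[res] = "flexible"
            notes[res] = "side-chain evidence only"
        else:
            calls[res] = "unobserved"
    return RigidityProfile(calls, evidence, notes)


@dataclass(frozen=True)
class DynamicSegments:
    """Three inclusive ranges tiling the construct; None when empty."""

    n_flex: tuple[int, int] | None
    rigid_core: tuple[int, int] | None
    c_flex: tuple[int, int] | None

    def as_dict(self) -> dict:
        return {
            "n_flex": [int(x) for x in self.n_flex] if self.n_flex else None,
            "rigid_core": [int(x) for x in self.rigid_core]
            if self.rigid_core else None,
            "c_flex": [int(x) for x in self.c_flex] if self.c_flex else None,
        }


def segment_profile(profile: RigidityProfile, min_run: int = 3) -> DynamicSegments:
    """Split a profile into flexible N-arm, rigid core, flexible C-arm.

    The rigid core is the longest contiguous run that starts and ends on a
    rigid/both call, contains no flexible call, and has length >= min_run;
    unobserved residues inside the run are absorbed (spectral overlap is
    not evidence of flexibility).  Ties favour the earliest run.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    residues = profile.residues()
    if not residues:
        return DynamicSegments(None, None, None)
    rigidlike = {r for r in residues if profile.calls[r] in ("rigid", "both")}
    flexible = {r for r in residues if profile.calls[r] == "flexible"}
    best: tuple[int, int] | None = None
    start = None
    last_rigid = None
    for r in residues + [None]:
        if r is not None and r in rigidlike:
            if start is None:
                start = r
            last_rigid = r
            continue
        boundary = r is None or r in flexible
        if boundary and start is not None:
            run = (start, last_rigid)
            if run[1] - run[0] + 1 >= min_run and (
                best is None or run[1] - run[0] > best[1] - best[0]
            ):
                best = run
            start, last_rigid = None, None
        # unobserved inside a candidate run: keep going
    lo, hi = residues[0], residues[-1]
    if best is None:
        return DynamicSegments((lo, hi), None, None)
    n_flex = (lo, best[0] - 1) if best[0] > lo else None
    c_flex = (best[1] + 1, hi) if best[1] < hi else None
    return DynamicSegments(n_flex, best, c_flex)


def helix_length(first_residue: int, last_residue: int,
                 rise_per_residue_A: float = 1.5) -> float:
    """Length in nm of an ideal alpha-helix spanning the inclusive range.

    Counts residues inclusively: (last - first + 1) * rise / 10.
    """
    if last_residue < first_residue:
        raise ValueError("last residue before first")
    return (last_residue - first_residue + 1) * rise_per_residue_A / 10.0


def intensity_ratio(free: PeakList, bound: PeakList,
                    tol: float | None = None) -> float:
    """Mean fractional signal decrease between matched free/bound peaks.

    Pairs peaks by assignment label (or by nearest position within ``tol``
    ppm when labels are absent) and returns 1 - mean(bound / free) over
    pairs with positive free intensity.
    """
    free_by = free.by_label()
    bound_by = bound.by_label()
    pairs: list[tuple[Peak, Peak]] = [
        (free_by[k], bound_by[k]) for k in free_by if k in bound_by
    ]
    if not pairs and tol is not None:
        for pf in free.peaks:
            cands = [
                pb for pb in bound.peaks
                if max(abs(a - b) for a, b in zip(pf.position, pb.position)) <= tol
            ]
            if cands:
                pairs.append((pf, cands[0]))
    ratios = [pb.intensity / pf.intensity for pf, pb in pairs if pf.intensity > 0]
    if not ratios:
        raise ValueError("no matched free/bound peak pairs")
    return 1.0 - float(np.mean(ratios))
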