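"""Peak matching, rigidity classification, segmentation and geometry."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtdyn.editing import (
    DynamicSegments,
    classify_residues,
    helix_length,
    intensity_ratio,
    match_peaks,
    segment_profile,
    RigidityProfile,
)
from mtdyn.peaks import Peak, PeakList
from mtdyn.synth import (
    NoiseModel,
    RigidityGroundTruth,
    generate_attenuation_pair,
    generate_editing_peaklists,
    nh_table,
)
from mtdyn.fixtures import rigidity_truth, ssnmr_noise


def brute_force_match(peaklist, table, tol_h, tol_c):
    """Independent oracle: exhaustive scan of every (peak, target) pair."""
    from mtdyn.synth import ch_pairs

    targets = []
    for res in table.residues():
        for c_atom, h_atom in ch_pairs(table, res):
            targets.append((res, c_atom, h_atom,
                            table.get(res, c_atom), table.get(res, h_atom)))
    result = {}
    for i, p in enumerate(peaklist.peaks):
        best = None
        for res, ca, ha, c, h in targets:
            d = max(abs(p.position[0] - c) / tol_c,
                    abs(p.position[1] - h) / tol_h)
            if d <= 1.0 and (best is None or (d, res) < (best[0], best[1])):
                best = (d, res, ca, ha)
        if best is not None:
            result[i] = (best[1], best[2], best[3])
    return result


class TestMatching:
    def test_empty_peak_list(self, shift_table):
        ms = match_peaks(PeakList(2, []), shift_table)
        assert ms.matches == [] and ms.unmatched == []

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_agrees_with_brute_force(self, shift_table, seed):
        rng = np.random.default_rng(seed)
        rows = shift_table.df
        peaks = []
        for _ in range(20):
            row = rows.iloc[rng.integers(len(rows))]
            peaks.append(Peak((row["shift"] + rng.normal(0, 0.3),
                               rng.uniform(0, 5)), 1.0))
        pl = PeakList(2, peaks)
        ms = match_peaks(pl, shift_table, tol_h=0.05, tol_c=0.5)
        oracle = brute_force_match(pl, shift_table, 0.05, 0.5)
        got = {m.peak_index: (m.residue_number, *m.atoms) for m in ms.matches}
        assert got == oracle

    def test_order_permutation_invariance(self, shift_table):
        rng = np.random.default_rng(9)
        peaks = [Peak((rng.uniform(15, 65), rng.uniform(0.5, 4.5)), 1.0)
                 for _ in range(30)]
        fwd = match_peaks(PeakList(2, peaks), shift_table)
        rev = match_peaks(PeakList(2, peaks[::-1]), shift_table)
        a = {tuple(p.position): (m.residue_number, m.atoms)
             for m in fwd.matches for p in [peaks[m.peak_index]]}
        b = {tuple(rev.peaklist.peaks[m.peak_index].position):
             (m.residue_number, m.atoms) for m in rev.matches}
        assert a == b

    def test_ile86_cb_hb_solution_position_matches(self, shift_table):
        # the lone Ile's CB-HB correlation observed in the rigid channel
        pos = (shift_table.get(86, "CB"), shift_table.get(86, "HB"))
        ms = match_peaks(PeakList(2, [Peak(pos, 1.0)]), shift_table)
        assert ms.matches[0].residue_number == 86
        assert ms.matches[0].atoms == ("CB", "HB")


class TestClassification:
    def test_unmatched_residue_is_unobserved(self, sequence, shift_table):
        empty = match_peaks(PeakList(2, []), shift_table)
        prof = classify_residues(empty, empty, residues=[59, 60])
        assert prof.calls == {59: "unobserved", 60: "unobserved"}

    def test_noiseless_closed_loop_is_exact(self, sequence, shift_table):
        truth = rigidity_truth()
        dip, sca = generate_editing_peaklists(sequence, shift_table, truth,
                                              NoiseModel(seed=5))
        prof = classify_residues(match_peaks(dip, shift_table),
                                 match_peaks(sca, shift_table),
                                 residues=[r.number for r in sequence])
        for r in sequence:
            assert prof.calls[r.number] == truth.states[r.number]

    def test_noisy_recovery_rate(self, sequence, shift_table):
        truth = rigidity_truth()
        rates = []
        for s in range(10):
            dip, sca = generate_editing_peaklists(sequence, shift_table, truth,
                                                  ssnmr_noise(s))
            prof = classify_residues(match_peaks(dip, shift_table),
                                     match_peaks(sca, shift_table),
                                     residues=[r.number for r in sequence])
            ok = sum(prof.calls[r.number] == truth.states[r.number]
                     for r in sequence)
            rates.append(ok / len(sequence))
        assert np.mean(rates) >= 0.95

    def test_cterminal_dynamics_include_k154_and_h167(self, sequence,
                                                      shift_table):
        # the study ground truth marks these C-terminal residues mobile
        truth = rigidity_truth()
        dip, sca = generate_editing_peaklists(sequence, shift_table, truth,
                                              NoiseModel(seed=2))
        prof = classify_residues(match_peaks(dip, shift_table),
                                 match_peaks(sca, shift_table),
                                 residues=[r.number for r in sequence])
        assert prof.calls[154] == "flexible"
        assert prof.calls[167] == "flexible"

    def test_mobile_side_chain_annotation(self, sequence, shift_table):
        truth = rigidity_truth()  # I86: rigid backbone, flexible methyls
        dip, sca = generate_editing_peaklists(sequence, shift_table, truth,
                                              NoiseModel(seed=2))
        prof = classify_residues(match_peaks(dip, shift_table),
                                 match_peaks(sca, shift_table),
                                 residues=[r.number for r in sequence])
        assert prof.calls[86] == "rigid"
        assert "mobile side chain" in prof.annotations.get(86, "")


def brute_force_segments(calls, min_run):
    """Oracle: enumerate all candidate cores, keep the longest valid one."""
    residues = sorted(calls)
    rigidlike = {r for r in residues if calls[r] in ("rigid", "both")}
    flexible = {r for r in residues if calls[r] == "flexible"}
    best = None
    for i in residues:
        for j in residues:
            if j < i or i not in rigidlike or j not in rigidlike:
                continue
            if any(r in flexible for r in range(i, j + 1)):
                continue
            if j - i + 1 < min_run:
                continue
            if best is None or j - i > best[1] - best[0]:
                best = (i, j)
    lo, hi = residues[0], residues[-1]
    if best is None:
        return DynamicSegments((lo, hi), None, None)
    return DynamicSegments(
        (lo, best[0] - 1) if best[0] > lo else None,
        best,
        (best[1] + 1, hi) if best[1] < hi else None,
    )


class TestSegmentation:
    @staticmethod
    def _profile(calls):
        return RigidityProfile(calls, {r: {"dipolar": set(), "scalar": set()}
                                       for r in calls})

    def test_all_rigid_gives_full_core(self):
        calls = {r: "rigid" for r in range(59, 171)}
        seg = segment_profile(self._profile(calls))
        assert seg.as_dict() == {"n_flex": None, "rigid_core": [59, 170],
                                 "c_flex": None}

    def test_all_flexible_gives_empty_core(self):
        calls = {r: "flexible" for r in range(59, 80)}
        seg = segment_profile(self._profile(calls))
        assert seg.rigid_core is None

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_profiles(self, seed):
        rng = np.random.default_rng(seed)
        states = ["rigid", "flexible", "both", "unobserved"]
        for _ in range(25):
            n = rng.integers(5, 40)
            calls = {int(60 + i): states[rng.integers(4)] for i in range(n)}
            got = segment_profile(self._profile(calls), min_run=3)
            want = brute_force_segments(calls, min_run=3)
            assert got == want, calls

    def test_reported_boundary_profile_segments(self):
        calls = {r: "flexible" for r in range(59, 70)}
        calls.update({r: "rigid" for r in range(70, 149)})
        calls.update({r: "flexible" for r in range(149, 171)})
        calls[100] = "unobserved"  # overlap gap absorbed into the core
        seg = segment_profile(self._profile(calls))
        assert seg.n_flex == (59, 69)
        assert seg.rigid_core == (70, 148)
        assert seg.c_flex == (149, 170)


class TestHelixGeometry:
    def test_printed_spans(self):
        assert helix_length(63, 151) == pytest.approx(13.35)
        assert helix_length(66, 148) == pytest.approx(12.45)

    def test_single_residue(self):
        assert helix_length(8, 8) == pytest.approx(0.15)

    def test_reversed_range_errors(self):
        with pytest.raises(ValueError):
            helix_length(10, 9)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(1, 300), st.integers(0, 100), st.integers(0, 100))
    def test_length_is_additive(self, a, i, j):
        b = a + i
        c = b + 1 + j
        total = helix_length(a, b) + helix_length(b + 1, c)
        assert total == pytest.approx(helix_length(a, c))


class TestIntensityRatio:
    def test_identical_lists_give_zero(self, shift_table):
        free, _ = generate_attenuation_pair(nh_table(shift_table), 0.5,
                                            NoiseModel(seed=0))
        assert intensity_ratio(free, free) == pytest.approx(0.0)

    @pytest.mark.parametrize("fraction", [0.9, 0.25, 0.6667])
    def test_noiseless_round_trip_is_exact(self, shift_table, fraction):
        free, bound = generate_attenuation_pair(nh_table(shift_table),
                                                fraction, NoiseModel(seed=0))
        assert intensity_ratio(free, bound) == pytest.approx(fraction,
                                                             abs=1e-12)

    def test_no_pairs_errors(self):
        with pytest.raises(ValueError):
            intensity_ratio(PeakList(2, []), PeakList(2, []))
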