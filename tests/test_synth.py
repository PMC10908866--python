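"""Synthetic generators: determinism, channel selection, raster linearity,
titration limits, calorimetry shapes and attenuation pairs."""
import numpy as np
import pytest

from mtdyn.binding import ITCSchedule
from mtdyn.peaks import PeakList
from mtdyn.sequence import parse_sequence
from mtdyn.spectrum import AxesSpec, RegionDefinition
from mtdyn.synth import (
    BindingGroundTruth,
    GenerationError,
    NoiseModel,
    RigidityGroundTruth,
    generate_anisotropy_series,
    generate_attenuation_pair,
    generate_editing_peaklists,
    generate_itc_thermogram,
    generate_shift_table,
    generate_titration_series,
    nh_table,
    rasterize,
)

NOISY = NoiseModel(seed=7, jitter_h=0.01, jitter_c=0.1, intensity_rel_sd=0.05,
                   baseline_sd=0.02)


def _truth(sequence, flexible=()):
    return RigidityGroundTruth.from_segments(sequence, flexible=list(flexible))


class TestDeterminism:
    def test_same_seed_bit_identical(self, sequence, shift_table):
        truth = _truth(sequence, [(59, 70)])
        out = [
            generate_editing_peaklists(sequence, shift_table, truth, NOISY)
            for _ in range(2)
        ]
        assert out[0][0].write() == out[1][0].write()
        assert out[0][1].write() == out[1][1].write()

    def test_itc_and_anisotropy_deterministic(self):
        truth = BindingGroundTruth(kd_uM=5.0)
        a = generate_itc_thermogram(ITCSchedule(), truth,
                                    NoiseModel(seed=3, baseline_sd=0.3))
        b = generate_itc_thermogram(ITCSchedule(), truth,
                                    NoiseModel(seed=3, baseline_sd=0.3))
        assert np.array_equal(a.heats_uJ, b.heats_uJ)
        sa = generate_anisotropy_series(1.0, [0, 10, 50], truth,
                                        NoiseModel(seed=3), anisotropy_sd=0.01)
        sb = generate_anisotropy_series(1.0, [0, 10, 50], truth,
                                        NoiseModel(seed=3), anisotropy_sd=0.01)
        assert np.array_equal(sa.anisotropy, sb.anisotropy)


class TestEditingLists:
    def test_all_rigid_gives_empty_scalar_list(self, sequence, shift_table):
        dip, sca = generate_editing_peaklists(
            sequence, shift_table, _truth(sequence), NoiseModel(seed=0))
        assert len(sca) == 0 and len(dip) > 0

    def test_flexible_termini_define_scalar_residue_set(self, sequence,
                                                        shift_table):
        # mobile arms at 59-70 and 148-170 appear only in the scalar channel
        truth = _truth(sequence, [(59, 70), (148, 170)])
        dip, sca = generate_editing_peaklists(sequence, shift_table, truth,
                                              NoiseModel(seed=0))
        scalar_residues = {p.assignment[0] for p in sca.peaks}
        assert scalar_residues == set(range(59, 71)) | set(range(148, 171))
        assert not scalar_residues & {p.assignment[0] for p in dip.peaks}

    def test_missing_shift_coverage_errors(self, library):
        seq = parse_sequence("AG", 1)
        table = generate_shift_table(seq, library, seed=0)
        bad = table.df[table.df["residue_number"] != 1]
        from mtdyn.shifts import ChemicalShiftTable
        with pytest.raises(GenerationError, match="residue 1"):
            generate_editing_peaklists(seq, ChemicalShiftTable(bad),
                                       _truth(seq), NoiseModel(seed=0))


class TestRasterize:
    AXES = AxesSpec(h_range=(0.0, 6.0), c_range=(10.0, 70.0), n_h=700, n_c=700)

    def test_empty_list_is_pure_noise_with_zero_mean(self):
        spec = rasterize(PeakList(2, []), self.AXES,
                         NoiseModel(seed=1, baseline_sd=0.05))
        assert abs(spec.data.mean()) < 3 * 0.05 / np.sqrt(spec.data.size)

    def test_unit_peak_integral_within_3_fwhm(self):
        from mtdyn.peaks import Peak
        pl = PeakList(2, [Peak((40.0, 3.0), 1.0, (0.5, 0.17))])
        spec = rasterize(pl, self.AXES, NoiseModel(seed=0))
        region = RegionDefinition("box", (3.0 - 0.51, 3.0 + 0.51),
                                  (40.0 - 1.5, 40.0 + 1.5))
        ci, hi = spec.region_slice(region)
        integral = spec.data[ci, hi].sum() * spec.pixel_area
        assert integral == pytest.approx(1.000, abs=0.01)

    def test_two_identical_peaks_double_the_integral(self):
        from mtdyn.peaks import Peak
        one = PeakList(2, [Peak((40.0, 3.0), 1.0, (0.5, 0.17))])
        two = PeakList(2, [Peak((40.0, 3.0), 1.0, (0.5, 0.17)),
                           Peak((40.3, 3.1), 1.0, (0.5, 0.17))])
        region = RegionDefinition("box", (1.5, 4.5), (37.0, 43.0))
        spec1 = rasterize(one, self.AXES, NoiseModel(seed=0))
        spec2 = rasterize(two, self.AXES, NoiseModel(seed=0))
        ci, hi = spec1.region_slice(region)
        i1 = spec1.data[ci, hi].sum() * spec1.pixel_area
        i2 = spec2.data[ci, hi].sum() * spec2.pixel_area
        assert i2 == pytest.approx(2 * i1, rel=1e-6)

    def test_peak_outside_axes_errors(self):
        from mtdyn.peaks import Peak
        pl = PeakList(2, [Peak((90.0, 3.0), 1.0, (0.5, 0.17))])
        with pytest.raises(GenerationError, match="outside axes"):
            rasterize(pl, self.AXES, NoiseModel(seed=0))


class TestTitration:
    TRUTH = BindingGroundTruth(kd_uM=100.0)

    def test_zero_ligand_equals_free_shifts(self, shift_table):
        table = nh_table(shift_table)
        out = generate_titration_series(table, {86: (0.2, 1.0)}, [0.0], 50.0,
                                        self.TRUTH, NoiseModel(seed=0))
        assert len(out) == 1
        for p in out[0].peaks:
            res = p.assignment[0]
            assert p.position[0] == pytest.approx(table.get(res, "H"), abs=1e-4)
            assert p.position[1] == pytest.approx(table.get(res, "N"), abs=1e-4)

    def test_saturation_limit_reaches_ddmax(self, shift_table):
        table = nh_table(shift_table)
        out = generate_titration_series(table, {86: (0.2, 1.0)}, [0.0, 1e7],
                                        50.0, self.TRUTH, NoiseModel(seed=0))
        free = out[0].by_label()
        sat = out[1].by_label()
        lab = [k for k in free if k.startswith("I86")][0]
        assert sat[lab].position[0] - free[lab].position[0] == pytest.approx(
            0.2, abs=1e-3)
        assert sat[lab].position[1] - free[lab].position[1] == pytest.approx(
            1.0, abs=1e-3)

    def test_negative_concentration_rejected(self, shift_table):
        with pytest.raises(GenerationError):
            generate_titration_series(nh_table(shift_table), {}, [-1.0], 50.0,
                                      self.TRUTH, NoiseModel(seed=0))

    def test_prolines_emit_no_amide_peak(self, sequence, shift_table):
        out = generate_titration_series(nh_table(shift_table), {}, [0.0], 50.0,
                                        self.TRUTH, NoiseModel(seed=0))
        residues = {p.assignment[0] for p in out[0].peaks}
        prolines = {r.number for r in sequence if r.code == "P"}
        assert not residues & prolines


class TestITCGenerator:
    def test_zero_enthalpy_gives_zero_heats(self):
        truth = BindingGroundTruth(kd_uM=1.0, dh_kcal_mol=0.0)
        th = generate_itc_thermogram(ITCSchedule(), truth, NoiseModel(seed=0))
        assert np.allclose(th.heats_uJ, 0.0)

    def test_tight_binding_step_shape(self):
        # near-stoichiometric limit: constant heats, then a drop at ratio n
        truth = BindingGroundTruth(kd_uM=1e-4, n=1.0, dh_kcal_mol=-8.0)
        sched = ITCSchedule()
        th = generate_itc_thermogram(sched, truth, NoiseModel(seed=0))
        ratio = sched.molar_ratio()
        before = th.heats_uJ[ratio < 0.8]
        after = th.heats_uJ[ratio > 1.2]
        assert np.ptp(before) < 0.05 * abs(before.mean())
        assert np.abs(after).max() < 0.02 * np.abs(before).max()

    def test_printed_schedule_sigmoid_inflects_near_n(self):
        truth = BindingGroundTruth(kd_uM=0.94, n=0.51, dh_kcal_mol=-8.0)
        sched = ITCSchedule(cell_volume_uL=164.0, cell_conc_uM=15.0,
                            syringe_conc_uM=150.0, injection_volume_uL=2.0,
                            n_injections=25)
        th = generate_itc_thermogram(sched, truth, NoiseModel(seed=0))
        ratio = sched.molar_ratio()
        # steepest decrease of the heat curve sits near molar ratio n
        slopes = np.diff(th.heats_uJ) / np.diff(ratio)
        inflection = ratio[np.argmax(slopes[:-3])]
        assert inflection == pytest.approx(truth.n, abs=0.25)


class TestAnisotropyGenerator:
    TRUTH = BindingGroundTruth(kd_uM=91.3, r_free=0.05, r_bound=0.20)

    def test_zero_titrant_gives_r_free(self):
        s = generate_anisotropy_series(1.0, [0.0, 50.0], self.TRUTH,
                                       NoiseModel(seed=0))
        assert s.anisotropy[0] == pytest.approx(0.05)

    def test_saturation_reaches_r_bound(self):
        s = generate_anisotropy_series(1.0, [0.0, 1e7], self.TRUTH,
                                       NoiseModel(seed=0))
        assert s.anisotropy[-1] == pytest.approx(0.20, abs=1e-4)


class TestAttenuationPair:
    def test_zero_fraction_identical(self, shift_table):
        free, bound = generate_attenuation_pair(nh_table(shift_table), 0.0,
                                                NoiseModel(seed=0))
        assert free.write() == bound.write().replace("bound", "free") or \
            [p.intensity for p in free.peaks] == [p.intensity for p in bound.peaks]

    def test_full_attenuation_zeroes_bound(self, shift_table):
        _, bound = generate_attenuation_pair(nh_table(shift_table), 1.0,
                                             NoiseModel(seed=0))
        assert all(p.intensity == 0.0 for p in bound.peaks)

    def test_fraction_out_of_range_rejected(self, shift_table):
        with pytest.raises(GenerationError):
            generate_attenuation_pair(nh_table(shift_table), 1.2,
                                      NoiseModel(seed=0))
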