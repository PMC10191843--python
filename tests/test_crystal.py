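"""Structure factors, maps, difference coefficients, scaling and model IO."""

import numpy as np
import pytest

from kokflash.crystal import (
    FORM_FACTORS,
    Atom,
    AtomicModel,
    ReflectionSet,
    UnitCell,
    WeightingScheme,
    compute_structure_factors,
    difference_coefficients,
    direct_summation,
    fo_fo_difference,
    hkl_grid,
    map_from_coefficients,
    read_model,
    scale_to_reference,
    sigma_normalize,
    write_model,
)

CELL = UnitCell(20.0, 20.0, 20.0)


def single_atom_model(element="C", pos=(0.0, 0.0, 0.0), occ=1.0, b=0.0):
    return AtomicModel(
        cell=CELL,
        atoms=[Atom(element, np.array(pos), occ, b, ("A", 1, "UNK", "X1"))],
    )


class TestFormFactors:
    @pytest.mark.parametrize("element,z", [("C", 6), ("O", 8), ("Mn", 25), ("Ca", 20)])
    def test_zero_angle_value_near_electron_count(self, element, z):
        f0 = FORM_FACTORS.evaluate(element, np.array([0.0]))[0]
        assert f0 == pytest.approx(z, rel=0.02)

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError, match="Xq"):
            FORM_FACTORS.coefficients("Xq")


class TestStructureFactors:
    def test_atom_at_origin_has_zero_phases_and_f_amplitude(self):
        sf = compute_structure_factors(single_atom_model(), 3.0)
        np.testing.assert_allclose(np.exp(1j * np.radians(sf.phase)).imag, 0, atol=1e-12)
        f = FORM_FACTORS.evaluate("C", sf.s2)
        np.testing.assert_allclose(sf.amplitude, np.abs(f), rtol=1e-12)

    def test_amplitudes_linear_in_occupancy(self):
        full = compute_structure_factors(single_atom_model(occ=1.0), 3.0)
        half = compute_structure_factors(single_atom_model(occ=0.5), 3.0)
        np.testing.assert_allclose(half.amplitude, 0.5 * full.amplitude, rtol=1e-12)

    def test_symmetric_atom_pair_cosine_closed_form(self):
        """Two identical atoms at +x and -x: |F| = 2 f(s) |cos(2 pi h.x)|."""
        x = np.array([0.11, 0.0, 0.0])
        model = AtomicModel(cell=CELL, atoms=[
            Atom("C", x, 1.0, 0.0, ("A", 1, "UNK", "C1")),
            Atom("C", -x % 1.0, 1.0, 0.0, ("A", 1, "UNK", "C2")),
        ])
        sf = compute_structure_factors(model, 2.5)
        f = FORM_FACTORS.evaluate("C", sf.s2)
        expected = 2.0 * f * np.abs(np.cos(2 * np.pi * sf.hkl @ x))
        np.testing.assert_allclose(sf.amplitude, expected, rtol=0, atol=1e-10 * f.max())

    def test_friedel_symmetry(self, toy_s3):
        hkl = hkl_grid(toy_s3.cell, 3.0)[:50]
        args = (
            [a.element for a in toy_s3.atoms],
            toy_s3.positions_frac(),
            np.array([a.occupancy for a in toy_s3.atoms]),
            np.array([a.b_iso for a in toy_s3.atoms]),
        )
        F_pos = direct_summation(toy_s3.cell, hkl, *args)
        F_neg = direct_summation(toy_s3.cell, -hkl, *args)
        np.testing.assert_allclose(F_neg, np.conj(F_pos), rtol=1e-10)

    def test_merged_model_is_complex_sum_of_parts(self, toy_s3, rng):
        n = len(toy_s3)
        half = n // 2
        a = AtomicModel(cell=toy_s3.cell, atoms=toy_s3.atoms[:half])
        b = AtomicModel(cell=toy_s3.cell, atoms=toy_s3.atoms[half:])
        sf_all = compute_structure_factors(toy_s3, 2.5)
        sf_a = compute_structure_factors(a, 2.5)
        sf_b = compute_structure_factors(b, 2.5)
        np.testing.assert_allclose(
            sf_all.complex_values(),
            sf_a.complex_values() + sf_b.complex_values(),
            atol=1e-8 * sf_all.amplitude.max(),
        )

    def test_agrees_with_gemmi_calculator(self):
        """Independent oracle: gemmi's direct X-ray structure-factor calculator."""
        import gemmi

        model = AtomicModel(cell=CELL, atoms=[
            Atom("Mn", np.array([0.25, 0.25, 0.25]), 1.0, 15.0, ("A", 1, "UNK", "MN")),
            Atom("O", np.array([0.35, 0.27, 0.25]), 0.7, 20.0, ("A", 1, "UNK", "O")),
        ])
        st = gemmi.Structure()
        st.cell = CELL.to_gemmi()
        st.spacegroup_hm = "P 1"
        md = gemmi.Model("1")
        ch = gemmi.Chain("A")
        res = gemmi.Residue()
        res.name = "UNK"
        res.seqid = gemmi.SeqId(1, " ")
        for atom in model.atoms:
            ga = gemmi.Atom()
            ga.name = atom.label[3]
            ga.element = gemmi.Element(atom.element)
            ga.pos = gemmi.Position(*CELL.orthogonalize(atom.position))
            ga.occ = atom.occupancy
            ga.b_iso = atom.b_iso
            res.add_atom(ga)
        ch.add_residue(res)
        md.add_chain(ch)
        st.add_model(md)
        st.setup_entities()
        calc = gemmi.StructureFactorCalculatorX(st.cell)
        sf = compute_structure_factors(model, 2.5)
        for i in range(0, len(sf), 97):
            ref = complex(calc.calculate_sf_from_model(st[0], [int(v) for v in sf.hkl[i]]))
            assert sf.complex_values()[i] == pytest.approx(ref, rel=1e-6)

    def test_unknown_element_named_in_error(self):
        model = single_atom_model()
        model.atoms[0].element = "Zz"
        with pytest.raises(ValueError, match="Zz"):
            compute_structure_factors(model, 3.0)


class TestMaps:
    def test_zero_coefficients_give_zero_map(self):
        coeffs = ReflectionSet(CELL, np.array([[1, 0, 0]]), np.array([0.0]),
                               phase=np.array([0.0]))
        m = map_from_coefficients(coeffs, resolution_limit=5.0)
        assert m.rms == 0.0
        with pytest.raises(ValueError, match="zero map"):
            sigma_normalize(m)

    def test_single_coefficient_is_cosine_wave(self):
        A = 7.0
        coeffs = ReflectionSet(CELL, np.array([[2, 0, 0]]), np.array([A]),
                               phase=np.array([0.0]))
        m = map_from_coefficients(coeffs, grid_spacing=1.0, resolution_limit=5.0)
        assert m.values.max() == pytest.approx(2 * A / CELL.volume, rel=1e-9)
        x = np.arange(m.values.shape[0]) / m.values.shape[0]
        np.testing.assert_allclose(
            m.values[:, 0, 0], 2 * A / CELL.volume * np.cos(2 * np.pi * 2 * x),
            atol=1e-12,
        )

    def test_map_peaks_at_atom_sites(self, toy_s3):
        sf = compute_structure_factors(toy_s3, 2.0)
        m = map_from_coefficients(sf)
        vals = m.interpolate(toy_s3.positions_frac())
        # every atom sits on density far above the cell rms
        assert np.all(vals > 3.0 * m.rms)

    def test_sigma_normalize_scale_invariance(self, rng):
        vals = rng.normal(size=(8, 8, 8))
        vals -= vals.mean()
        m1 = sigma_normalize(type(self)._mk(vals))
        m2 = sigma_normalize(type(self)._mk(10.0 * vals))
        np.testing.assert_allclose(m1.values, m2.values, atol=1e-12)
        assert m1.rms == pytest.approx(1.0)

    @staticmethod
    def _mk(vals):
        from kokflash.crystal import MapGrid

        return MapGrid(cell=CELL, values=vals)


class TestDifferenceCoefficients:
    def _pair(self, fo, fc, phase=0.0):
        hkl = np.array([[1, 2, 3]])
        fobs = ReflectionSet(CELL, hkl, np.array([fo]))
        fcalc = ReflectionSet(CELL, hkl, np.array([fc]), phase=np.array([phase]))
        return fobs, fcalc

    def test_equal_amplitudes_vanish(self):
        fobs, fcalc = self._pair(100.0, 100.0)
        out = difference_coefficients(fobs, fcalc, kind="mFo-DFc")
        assert out.amplitude[0] == pytest.approx(0.0, abs=1e-12)

    def test_simple_arithmetic(self):
        fobs, fcalc = self._pair(110.0, 100.0)
        out = difference_coefficients(fobs, fcalc, kind="mFo-DFc")
        assert out.amplitude[0] == pytest.approx(10.0)
        assert out.phase[0] % 360 == pytest.approx(0.0, abs=1e-9)

    def test_negative_amplitude_stored_with_shifted_phase(self):
        fobs, fcalc = self._pair(90.0, 100.0, phase=30.0)
        out = difference_coefficients(fobs, fcalc, kind="mFo-DFc")
        assert out.amplitude[0] == pytest.approx(10.0)
        assert (out.phase[0] - 210.0) % 360 == pytest.approx(0.0, abs=1e-6)

    def test_2mfo_dfc_reduces_to_fc_when_amplitudes_match(self, toy_s3):
        fc = compute_structure_factors(toy_s3, 2.5)
        fobs = ReflectionSet(CELL := toy_s3.cell, fc.hkl, fc.amplitude)
        out = difference_coefficients(fobs, fc, kind="2mFo-DFc")
        np.testing.assert_allclose(out.amplitude, fc.amplitude, rtol=1e-12)
        np.testing.assert_allclose(
            np.exp(1j * np.radians(out.phase)), np.exp(1j * np.radians(fc.phase)),
            atol=1e-9,
        )

    def test_hkl_mismatch_lists_missing(self):
        fobs = ReflectionSet(CELL, np.array([[1, 0, 0]]), np.array([1.0]))
        fcalc = ReflectionSet(CELL, np.array([[0, 1, 0]]), np.array([1.0]),
                              phase=np.array([0.0]))
        with pytest.raises(ValueError, match="hkl mismatch"):
            difference_coefficients(fobs, fcalc)


class TestFoFoDifference:
    def test_identical_datasets_give_zero_map(self, toy_s3):
        sf = compute_structure_factors(toy_s3, 2.5)
        fobs = ReflectionSet(toy_s3.cell, sf.hkl, sf.amplitude)
        m = fo_fo_difference(fobs, fobs, toy_s3)
        assert m.rms == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetric_under_swap(self, toy_s3, rng):
        sf = compute_structure_factors(toy_s3, 2.5)
        a = ReflectionSet(toy_s3.cell, sf.hkl, sf.amplitude)
        b = ReflectionSet(toy_s3.cell, sf.hkl,
                          sf.amplitude * (1 + 0.05 * rng.normal(size=len(sf))))
        m_ab = fo_fo_difference(a, b, toy_s3)
        m_ba = fo_fo_difference(b, a, toy_s3)
        np.testing.assert_allclose(m_ab.values, -m_ba.values, atol=1e-12)

    def test_extra_water_appears_as_positive_peak(self, toy_s3):
        """A water present only at time t shows >= 3 sigma near its site."""
        site = np.array([0.25, 0.70, 0.30])
        extra = toy_s3.copy()
        extra.atoms.append(Atom("O", site, 1.0, 30.0, ("A", 999, "HOH", "O")))
        sf_t = compute_structure_factors(extra, 2.0)
        sf_ref = compute_structure_factors(toy_s3, 2.0)
        fobs_t = ReflectionSet(toy_s3.cell, sf_t.hkl, sf_t.amplitude)
        fobs_ref = ReflectionSet(toy_s3.cell, sf_ref.hkl, sf_ref.amplitude)
        m = sigma_normalize(fo_fo_difference(fobs_t, fobs_ref, toy_s3))
        assert m.interpolate(site)[0] >= 3.0


class TestScaling:
    def test_self_scaling_is_identity(self, toy_s3):
        sf = compute_structure_factors(toy_s3, 2.5)
        ds = ReflectionSet(toy_s3.cell, sf.hkl, sf.amplitude,
                           sigma=0.03 * sf.amplitude)
        out = scale_to_reference(ds, ds, n_bins=10)
        np.testing.assert_allclose(out.amplitude, ds.amplitude, rtol=1e-12)

    def test_doubled_dataset_scaled_by_half(self, toy_s3):
        sf = compute_structure_factors(toy_s3, 2.5)
        ref = ReflectionSet(toy_s3.cell, sf.hkl, sf.amplitude)
        ds = ReflectionSet(toy_s3.cell, sf.hkl, 2.0 * sf.amplitude)
        out = scale_to_reference(ds, ref, n_bins=8)
        np.testing.assert_allclose(out.amplitude, ref.amplitude, rtol=1e-12)

    def test_two_bin_scales_recovered(self):
        hkl = np.array([[0, 0, l] for l in range(1, 21)])
        amp = np.full(20, 50.0)
        ref = ReflectionSet(CELL, hkl, amp)
        # low-resolution half scaled by 2, high-resolution half by 0.5
        d = ref.d
        factor = np.where(d > np.median(d), 2.0, 0.5)
        ds = ReflectionSet(CELL, hkl, amp * factor)
        out = scale_to_reference(ds, ref, n_bins=2)
        np.testing.assert_allclose(out.amplitude, ref.amplitude, rtol=1e-12)

    def test_idempotent(self, toy_s3, rng):
        sf = compute_structure_factors(toy_s3, 2.5)
        ref = ReflectionSet(toy_s3.cell, sf.hkl, sf.amplitude)
        ds = ReflectionSet(toy_s3.cell, sf.hkl,
                           sf.amplitude * (1.5 + 0.1 * rng.normal(size=len(sf))))
        once = scale_to_reference(ds, ref, n_bins=6)
        twice = scale_to_reference(once, ref, n_bins=6)
        np.testing.assert_allclose(twice.amplitude, once.amplitude, rtol=1e-9)


class TestModelIO:
    def test_pdb_round_trip(self, toy_s3, tmp_path):
        path = tmp_path / "toy.pdb"
        write_model(toy_s3, path)
        back = read_model(path)
        assert {a.label for a in back.atoms} == {a.label for a in toy_s3.atoms}
        for orig in toy_s3.atoms:
            rb = back.atom(orig.label)
            np.testing.assert_allclose(
                toy_s3.cell.orthogonalize(rb.position),
                toy_s3.cell.orthogonalize(orig.position), atol=2e-3,
            )
            assert rb.occupancy == pytest.approx(orig.occupancy, abs=1e-6)
            assert rb.b_iso == pytest.approx(orig.b_iso, abs=1e-2)
            assert rb.element == orig.element

    def test_mmcif_round_trip_matches_pdb(self, toy_s3, tmp_path):
        p1, p2 = tmp_path / "toy.pdb", tmp_path / "toy.cif"
        write_model(toy_s3, p1)
        write_model(toy_s3, p2)
        a, b = read_model(p1), read_model(p2)
        np.testing.assert_allclose(a.positions_cart(), b.positions_cart(), atol=2e-3)

    def test_occupancy_column_preserved(self, tmp_path):
        model = single_atom_model(occ=0.40, b=22.0)
        path = tmp_path / "occ.pdb"
        write_model(model, path)
        back = read_model(path)
        assert back.atoms[0].occupancy == pytest.approx(0.40)
        assert back.atoms[0].b_iso == pytest.approx(22.0)

    def test_chain_case_preserved(self, tmp_path):
        model = AtomicModel(cell=CELL, atoms=[
            Atom("C", np.array([0.1, 0.1, 0.1]), 1.0, 10.0, ("A", 1, "UNK", "C1")),
            Atom("C", np.array([0.6, 0.6, 0.6]), 1.0, 10.0, ("a", 1, "UNK", "C1")),
        ])
        path = tmp_path / "chains.cif"
        write_model(model, path)
        back = read_model(path)
        assert {a.label[0] for a in back.atoms} == {"A", "a"}

    def test_malformed_file_rejected(self, tmp_path):
        bad = tmp_path / "bad.cif"
        bad.write_text("this is not a structure\n")
        with pytest.raises(ValueError):
            read_model(bad)

    def test_reflection_csv_round_trip(self, toy_s3, tmp_path):
        sf = compute_structure_factors(toy_s3, 2.5, sigma_frac=0.03)
        path = tmp_path / "refl.csv"
        sf.to_csv(path)
        back = ReflectionSet.from_csv(path, toy_s3.cell)
        np.testing.assert_array_equal(back.hkl, sf.hkl)
        np.testing.assert_allclose(back.amplitude, sf.amplitude, atol=1e-5)
        # byte-stable writer
        path2 = tmp_path / "refl2.csv"
        back.to_csv(path2)
        path3 = tmp_path / "refl3.csv"
        ReflectionSet.from_csv(path2, toy_s3.cell).to_csv(path3)
        assert path2.read_bytes() == path3.read_bytes()


def test_unit_cell_filter_flags_outliers():
    """The 1% lattice filter keeps cells within the threshold on every axis."""
    from kokflash.crystal import unit_cell_filter

    ref = UnitCell(117.0, 221.0, 309.0)
    cells = [
        UnitCell(117.5, 221.0, 309.0),   # 0.4% off: kept
        UnitCell(119.0, 221.0, 309.0),   # 1.7% off: rejected
        UnitCell(117.0, 223.5, 309.0),   # 1.1% off: rejected
        UnitCell(116.0, 219.0, 306.5),   # all within 1%: kept
    ]
    assert unit_cell_filter(cells, ref) == [True, False, False, True]
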