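"""Mixture model composition, restraints, refinement, omit maps and scans."""

import numpy as np
import pytest

from kokflash.crystal import Atom, AtomicModel, ReflectionSet, UnitCell
from kokflash.metrics import omit_peak_height
from kokflash.mixture import (
    Component,
    MixtureRefinement,
    MultiComponentModel,
    RefinementConfig,
    build_restraints,
    composite_structure_factors,
    estimate_ox_occupancy,
    estimate_population,
    omit_map,
    refine_primary,
)
from kokflash.simulate import (
    OX_LABEL,
    ScenarioConfig,
    default_restraints,
    interpolate_intermediate,
    make_oec_toy,
    simulate_timepoint,
)


def _noisy_fobs(model_or_mcm, resolution=2.0, noise=0.03, seed=3):
    from kokflash.crystal import compute_structure_factors

    if isinstance(model_or_mcm, MultiComponentModel):
        fc = composite_structure_factors(model_or_mcm, resolution)
    else:
        fc = compute_structure_factors(model_or_mcm, resolution)
    rng = np.random.default_rng(seed)
    sigma = noise * fc.amplitude
    amp = fc.amplitude if noise == 0 else np.maximum(
        fc.amplitude + rng.normal(size=len(fc)) * sigma, 0.0
    )
    return ReflectionSet(fc.cell, fc.hkl, amp,
                         sigma=sigma if noise else 0.03 * fc.amplitude)


class TestComposite:
    def test_single_component_equals_its_sf(self, toy_s3):
        mcm = MultiComponentModel([Component(toy_s3.copy(), 1.0, True, "p")])
        from kokflash.crystal import compute_structure_factors

        a = composite_structure_factors(mcm, 2.5)
        b = compute_structure_factors(toy_s3, 2.5)
        np.testing.assert_allclose(a.complex_values(), b.complex_values(), rtol=1e-12)

    def test_identical_halves_match_single_component(self, toy_s3):
        mcm = MultiComponentModel([
            Component(toy_s3.copy(), 0.5, True, "a"),
            Component(toy_s3.copy(), 0.5, False, "b"),
        ])
        single = MultiComponentModel([Component(toy_s3.copy(), 1.0, True, "a")])
        np.testing.assert_allclose(
            composite_structure_factors(mcm, 2.5).complex_values(),
            composite_structure_factors(single, 2.5).complex_values(),
            rtol=1e-12,
        )

    def test_extra_atom_contribution_scales_with_population(self, toy_s3, toy_s0):
        """A 0.65/0.35 mixture of models differing by one atom: that atom's
        amplitude contribution carries its host's population weight."""
        p = 0.65
        with_ox = MultiComponentModel([
            Component(toy_s3.copy(), p, True, "s3"),
            Component(toy_s0.copy(), 1 - p, False, "s0"),
        ])
        no_ox_model = toy_s3.without([OX_LABEL])
        without_ox = MultiComponentModel([
            Component(no_ox_model, p, True, "s3"),
            Component(toy_s0.copy(), 1 - p, False, "s0"),
        ])
        diff = (composite_structure_factors(with_ox, 2.5).complex_values()
                - composite_structure_factors(without_ox, 2.5).complex_values())
        from kokflash.crystal import compute_structure_factors

        ox_only = AtomicModel(cell=toy_s3.cell, atoms=[toy_s3.atom(OX_LABEL)])
        expected = p * compute_structure_factors(ox_only, 2.5).complex_values()
        np.testing.assert_allclose(diff, expected, atol=1e-9)

    def test_populations_must_sum_to_one(self, toy_s3):
        with pytest.raises(ValueError, match="sum to 1"):
            MultiComponentModel([Component(toy_s3.copy(), 0.9, True, "p")])


class TestRestraints:
    def test_empty_topology_empty_set(self, toy_s3):
        rs = build_restraints(toy_s3)
        assert len(rs) == 0

    def test_ideal_geometry_zero_residuals(self, toy_s3):
        rs = default_restraints(toy_s3)
        np.testing.assert_allclose(rs.residuals(toy_s3), 0.0, atol=1e-9)

    def test_unit_reduced_residual_for_esd_deviation(self):
        cell = UnitCell(20, 20, 20)
        a = Atom("C", np.array([0.0, 0, 0]), 1, 10, ("A", 1, "UNK", "C1"))
        b = Atom("C", np.array([0.075, 0, 0]), 1, 10, ("A", 1, "UNK", "C2"))
        model = AtomicModel(cell=cell, atoms=[a, b])
        rs = build_restraints(model, bonds=[(a.label, b.label, 1.4)], bond_esd=0.1)
        # bond is 1.5 A vs ideal 1.4: (0.1/0.1)^2 = 1
        assert rs.residuals(model)[0] ** 2 == pytest.approx(1.0, abs=1e-9)

    def test_dangling_reference_rejected(self, toy_s3):
        with pytest.raises(ValueError, match="unknown atom"):
            build_restraints(toy_s3, bonds=[(("A", 1, "FOO", "X"), OX_LABEL)])

    def test_angle_restraint_residual(self):
        cell = UnitCell(20, 20, 20)
        atoms = [
            Atom("C", np.array([0.1, 0.0, 0]), 1, 10, ("A", 1, "UNK", "C1")),
            Atom("C", np.array([0.0, 0.0, 0]), 1, 10, ("A", 1, "UNK", "C2")),
            Atom("C", np.array([0.0, 0.1, 0]), 1, 10, ("A", 1, "UNK", "C3")),
        ]
        model = AtomicModel(cell=cell, atoms=atoms)
        rs = build_restraints(
            model, angles=[(atoms[0].label, atoms[1].label, atoms[2].label, 80.0)],
            angle_esd=10.0,
        )
        # actual angle 90 deg vs ideal 80: reduced residual 1
        assert rs.residuals(model)[0] == pytest.approx(1.0, abs=1e-9)


class TestRefinement:
    def test_start_at_optimum_stays_put(self, toy_s3):
        mcm = MultiComponentModel([Component(toy_s3.copy(), 1.0, True, "p")])
        fobs = _noisy_fobs(toy_s3, noise=0.0)
        res = refine_primary(mcm, fobs, default_restraints(toy_s3))
        moved = np.linalg.norm(
            res.primary_model.positions_cart() - toy_s3.positions_cart(), axis=1
        )
        assert moved.max() < 1e-3
        assert res.r_after < 1e-4

    def test_recovers_jittered_coordinates_noiseless(self, toy_s3, rng):
        truth = toy_s3
        fobs = _noisy_fobs(truth, noise=0.0)
        jittered = truth.copy()
        for atom in jittered.atoms:
            atom.position = atom.position + truth.cell.fractionalize(
                rng.uniform(-0.3, 0.3, 3) / np.sqrt(3)
            )
        mcm = MultiComponentModel([Component(jittered, 1.0, True, "p")])
        res = refine_primary(mcm, fobs, default_restraints(truth))
        # P1 + amplitude-only data leave the origin free for a lone component
        assert res.primary_rmsd(truth, allow_origin_shift=True) < 0.02

    def test_group_b_offset_recovers_global_shift(self, toy_s3, toy_s0):
        """Fixed component whose true B is +10 A^2 above the model's."""
        hot_s0 = toy_s0.copy()
        for atom in hot_s0.atoms:
            atom.b_iso += 10.0
        truth = MultiComponentModel([
            Component(toy_s3.copy(), 0.6, True, "p"),
            Component(hot_s0, 0.4, False, "s0"),
        ])
        fobs = _noisy_fobs(truth, noise=0.0)
        start = MultiComponentModel([
            Component(toy_s3.copy(), 0.6, True, "p"),
            Component(toy_s0.copy(), 0.4, False, "s0"),
        ])
        res = refine_primary(start, fobs, default_restraints(toy_s3))
        assert res.group_b_offsets[0] == pytest.approx(10.0, abs=0.5)

    def test_monotone_descent_and_fixed_components_untouched(
        self, sim_1200, restraints_guess
    ):
        fobs, guess, _ = sim_1200
        before = [c.model.positions_frac().copy() for c in guess.fixed]
        res = refine_primary(guess, fobs, restraints_guess)
        assert res.target_trajectory[-1] <= res.target_trajectory[0]
        for prev, comp in zip(before, res.mcm_refined.fixed):
            assert np.array_equal(prev, comp.model.positions_frac())

    def test_summary_reports_key_quantities(self, refined_1200):
        text = refined_1200.summary()
        assert "R after" in text and "populations" in text
        assert "primary" in text

    def test_b_factors_bounded_below(self, sim_1200, restraints_guess):
        fobs, guess, _ = sim_1200
        res = refine_primary(guess, fobs, restraints_guess,
                             RefinementConfig(max_cycles=40, b_min=2.0))
        assert all(a.b_iso >= 2.0 for a in res.primary_model.atoms)


class TestOmitMap:
    def test_zero_occupancy_atom_leaves_no_peak(self, toy_s3):
        """Omitting an absent (occupancy 0) atom shows nothing at its site.

        A fully occupied atom is omitted alongside it so the noiseless
        difference map has a nonzero sigma scale to compare against.
        """
        from kokflash.simulate import WATER_LABELS

        model = toy_s3.copy()
        model.atom(OX_LABEL).occupancy = 0.0
        anchor = WATER_LABELS["W29"]  # far from Ox, so its ripples don't reach
        mcm = MultiComponentModel([Component(model, 1.0, True, "p")])
        fobs = _noisy_fobs(model, noise=0.0)
        m = omit_map(mcm, [OX_LABEL, anchor], fobs)
        at_ox = omit_peak_height(m, model.cell.orthogonalize(model.atom(OX_LABEL).position))
        at_anchor = omit_peak_height(m, model.cell.orthogonalize(model.atom(anchor).position))
        assert abs(at_ox) < 1.0
        assert at_anchor >= 4.0

    def test_fully_occupied_oxygen_noiseless_peak(self, toy_s3):
        mcm = MultiComponentModel([Component(toy_s3.copy(), 1.0, True, "p")])
        fobs = _noisy_fobs(toy_s3, noise=0.0)
        m = omit_map(mcm, [OX_LABEL], fobs)
        pos = toy_s3.cell.orthogonalize(toy_s3.atom(OX_LABEL).position)
        assert omit_peak_height(m, pos) >= 4.0

    def test_omitting_fixed_component_atom_rejected(self, sim_1200):
        _, guess, _ = sim_1200
        fixed_label = guess.fixed[0].model.atoms[0].label
        # the label also exists in the primary; use one that does not
        only_fixed = OX_LABEL  # present in primary and s3; use an s0-only check
        with pytest.raises(ValueError, match="not in the primary"):
            omit_map(guess, [("A", 1, "NOPE", "X")], _noisy_fobs(guess.primary.model))

    def test_raw_peak_density_linear_in_occupancy(self, toy_s3):
        """Difference density at the omitted site scales with occupancy.

        Measured on the raw (pre-sigma-normalization) map: in a small toy
        cell the omitted atom dominates the cell rms, so sigma-normalized
        heights are deliberately not compared here.
        """
        from kokflash.crystal import (
            compute_structure_factors,
            difference_coefficients,
            map_from_coefficients,
        )

        peaks = {}
        for occ in (1.0, 0.4):
            model = toy_s3.copy()
            model.atom(OX_LABEL).occupancy = occ
            fobs = _noisy_fobs(model, noise=0.03, seed=21)
            partial = model.without([OX_LABEL])
            fcalc = compute_structure_factors(partial, 2.0)
            m = map_from_coefficients(difference_coefficients(fobs, fcalc))
            pos = model.cell.fractionalize(
                model.cell.orthogonalize(model.atom(OX_LABEL).position)
            )
            peaks[occ] = m.interpolate(pos)[0]
        assert peaks[0.4] / peaks[1.0] == pytest.approx(0.4, rel=0.2)


@pytest.fixture(scope="module")
def two_variant_template(toy_s3):
    """Ox-bearing and Ox-free variants of one structure."""
    with_ox = toy_s3.copy()
    with_ox.component_tag = "with_ox"
    without = toy_s3.without([OX_LABEL])
    without.component_tag = "no_ox"
    return MultiComponentModel([
        Component(with_ox, 0.5, False, "with_ox"),
        Component(without, 0.5, True, "no_ox"),
    ])


class TestPopulationScan:

    def test_recovers_simulated_ox_fraction(self, toy_s3, two_variant_template):
        truth = toy_s3.copy()
        truth.atom(OX_LABEL).occupancy = 0.15
        fobs = _noisy_fobs(truth, noise=0.03, seed=9)
        best, profile = estimate_population(
            two_variant_template, "with_ox", fobs,
            grid=np.arange(0, 1.0001, 0.05),
            restraints=default_restraints(two_variant_template.primary.model),
            config=RefinementConfig(max_cycles=20, tol=1e-8),
        )
        assert best == pytest.approx(0.15, abs=0.05)
        assert len(profile) == 21

    def test_absent_truth_estimates_near_zero(self, toy_s3, two_variant_template):
        truth = toy_s3.without([OX_LABEL])
        fobs = _noisy_fobs(truth, noise=0.03, seed=10)
        best, _ = estimate_population(
            two_variant_template, "with_ox", fobs,
            grid=np.arange(0, 0.50001, 0.05),
            restraints=default_restraints(two_variant_template.primary.model),
            config=RefinementConfig(max_cycles=20, tol=1e-8),
        )
        assert best <= 0.05

    def test_scanning_absent_component_increases_r_monotonically(
        self, toy_s3, toy_s0
    ):
        """Adding population of a state absent from the truth only hurts."""
        truth = toy_s3
        fobs = _noisy_fobs(truth, noise=0.0)
        template = MultiComponentModel([
            Component(toy_s3.copy(), 0.9, True, "s3"),
            Component(toy_s0.copy(), 0.1, False, "s0"),
        ])
        _, profile = estimate_population(
            template, "s0", fobs, grid=[0.0, 0.2, 0.4, 0.6],
            config=RefinementConfig(max_cycles=15, tol=1e-8, refine_xyz=False,
                                    refine_b=False, group_b=False),
        )
        r = profile["r_factor"].to_numpy()
        assert np.all(np.diff(r) > 0)

    def test_empty_grid_rejected(self, two_variant_template, toy_s3):
        with pytest.raises(ValueError, match="empty"):
            estimate_population(two_variant_template, "with_ox",
                                _noisy_fobs(toy_s3), grid=[])

    def test_occupancy_scan_recovery_in_mixture(self, sim_1200, restraints_guess):
        """Ox occupancy in the standard 0.40/0.35/0.25 mixture within 0.05."""
        fobs, guess, truth = sim_1200
        best, _ = estimate_ox_occupancy(
            guess, OX_LABEL, fobs, np.arange(0, 1.0001, 0.05), restraints_guess
        )
        assert best == pytest.approx(truth.ox_occupancy, abs=0.05)
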