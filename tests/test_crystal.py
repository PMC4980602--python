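"""Synthetic crystal: symmetry, reflection lists, structure factors, noise."""

import gemmi
import numpy as np
import pytest

from nsad import crystal, physics
from nsad.crystal import (
    P212121,
    RUBREDOXIN_CELL,
    SymmetryOps,
    UnitCell,
    generate_toy_structure,
    reflection_list,
    simulate_unmerged,
    structure_factor,
    structure_factor_direct,
)


class TestSymmetry:
    def test_group_closure_and_size(self):
        assert len(P212121) == 4
        assert P212121.is_closed()

    def test_operators_match_gemmi_tables(self):
        """Hard-coded operators agree with the reference space-group library."""
        sg = gemmi.SpaceGroup("P 21 21 21")
        ours = {
            (tuple(R.ravel()), tuple(np.round(t % 1.0, 6)))
            for R, t in zip(P212121.R, P212121.t)
        }
        theirs = set()
        for op in sg.operations():
            R = np.array(op.rot) / op.DEN
            t = np.array(op.tran) / op.DEN
            theirs.add(
                (tuple(R.astype(int).ravel()), tuple(np.round(t % 1.0, 6)))
            )
        assert ours == theirs


class TestUnitCell:
    def test_volume_and_d_spacing(self):
        cell = UnitCell(10.0, 20.0, 40.0)
        assert cell.volume == 8000.0
        assert cell.d_spacing(np.array([[2, 0, 0]]))[0] == pytest.approx(5.0)

    def test_rejects_nonpositive_lengths(self):
        with pytest.raises(ValueError):
            UnitCell(0.0, 10.0, 10.0)


class TestGenerator:
    def test_same_seed_identical_models(self, cell):
        m1 = generate_toy_structure(120, cell, seed=7)
        m2 = generate_toy_structure(120, cell, seed=7)
        assert np.array_equal(m1.xyz, m2.xyz)
        assert np.array_equal(m1.b_iso, m2.b_iso)
        assert [a.isotope.label for a in m1.atoms] == [
            a.isotope.label for a in m2.atoms
        ]

    def test_different_seed_differs(self, cell):
        m1 = generate_toy_structure(50, cell, seed=1)
        m2 = generate_toy_structure(50, cell, seed=2)
        assert not np.array_equal(m1.xyz, m2.xyz)

    def test_anomalous_site_has_reference_b_real(self, cell, beam):
        model = generate_toy_structure(50, cell, seed=4)
        b = model.scattering_lengths(beam)
        assert b[model.anomalous_site].real == pytest.approx(-8.0)
        assert b[model.anomalous_site].imag > 8.0  # strong resonance b″

    def test_coordinates_in_unit_interval(self, default_model):
        assert np.all(default_model.xyz >= 0.0)
        assert np.all(default_model.xyz < 1.0)

    def test_b_factor_range(self, default_model):
        assert default_model.b_iso.min() >= 5.0
        assert default_model.b_iso.max() <= 20.0

    def test_rejects_too_few_atoms(self, cell):
        with pytest.raises(ValueError):
            generate_toy_structure(1, cell, seed=0)


class TestReflectionList:
    def test_count_matches_enumeration_oracle(self, cell):
        """Unique reflection count equals an independent brute-force loop."""
        d_min = 1.75
        n = 0
        hmax, kmax, lmax = (
            int(cell.a / d_min) + 1,
            int(cell.b / d_min) + 1,
            int(cell.c / d_min) + 1,
        )
        for h in range(hmax + 1):
            for k in range(kmax + 1):
                for l in range(lmax + 1):
                    if h == k == l == 0:
                        continue
                    if (h / cell.a) ** 2 + (k / cell.b) ** 2 + (
                        l / cell.c
                    ) ** 2 > 1 / d_min**2:
                        continue
                    axial = (h != 0) + (k != 0) + (l != 0) == 1
                    if axial and (h + k + l) % 2 == 1:
                        continue
                    n += 1
        refl = reflection_list(cell, d_min)
        assert len(refl) == n
        # close to the reference experiment's 5560 (ideal geometry runs ~2.5% high)
        assert abs(len(refl) - 5560) / 5560 < 0.03

    def test_screw_axis_absences(self, cell):
        refl = reflection_list(cell, 1.75)
        idx = set(map(tuple, refl[["h", "k", "l"]].to_numpy()))
        assert (3, 0, 0) not in idx
        assert (2, 0, 0) in idx
        assert (0, 5, 0) not in idx
        assert (0, 0, 7) not in idx

    def test_absences_match_gemmi(self, cell):
        """Our exclusion rule agrees with gemmi's systematic-absence test."""
        sg = gemmi.SpaceGroup("P 21 21 21")
        ops = sg.operations()
        refl = reflection_list(cell, 3.0)
        for hkl in map(tuple, refl[["h", "k", "l"]].to_numpy()[::7]):
            assert not ops.is_systematically_absent(list(hkl))
        assert ops.is_systematically_absent([3, 0, 0])

    def test_halving_dmin_scales_count_eightfold(self, cell):
        n_hi = len(reflection_list(cell, 1.75))
        n_lo = len(reflection_list(cell, 3.5))
        assert n_hi / n_lo == pytest.approx(8.0, rel=0.1)

    def test_too_large_dmin_warns_empty(self):
        with pytest.warns(UserWarning):
            refl = reflection_list(UnitCell(10, 10, 10), 12.0)
        assert len(refl) == 0


class TestStructureFactor:
    def test_matches_naive_direct_sum(self, small_model, beam):
        """Vectorized F equals an explicit per-atom, per-op summation."""
        cell = small_model.cell
        hkl = reflection_list(cell, 2.5)[["h", "k", "l"]].to_numpy()[::311]
        f_plus, f_minus = structure_factor(small_model, hkl, beam)
        b = small_model.scattering_lengths(beam)
        for row, fp, fm in zip(hkl, f_plus, f_minus):
            d = cell.d_spacing(np.array([row]))[0]
            acc_p = acc_m = 0j
            for i, atom in enumerate(small_model.atoms):
                dw = np.exp(-atom.b_iso / (4 * d * d))
                for R, t in zip(small_model.ops.R, small_model.ops.t):
                    x = R @ np.array(atom.xyz) + t
                    acc_p += atom.occupancy * b[i] * dw * np.exp(
                        2j * np.pi * np.dot(row, x)
                    )
                    acc_m += atom.occupancy * b[i] * dw * np.exp(
                        -2j * np.pi * np.dot(row, x)
                    )
            assert abs(fp - acc_p) <= 1e-10 * max(abs(acc_p), 1.0)
            assert abs(fm - acc_m) <= 1e-10 * max(abs(acc_m), 1.0)

    def test_friedel_law_without_absorption(self, cell, beam):
        model = generate_toy_structure(30, cell, seed=9, b_imag_override=0.0)
        hkl = reflection_list(cell, 2.5)[["h", "k", "l"]].to_numpy()[::101]
        f_plus, f_minus = structure_factor(model, hkl, beam)
        np.testing.assert_allclose(np.abs(f_plus), np.abs(f_minus), rtol=1e-12)

    def test_friedel_law_broken_with_absorption(self, small_model, beam):
        hkl = reflection_list(small_model.cell, 2.5)[["h", "k", "l"]].to_numpy()
        f_plus, f_minus = structure_factor(small_model, hkl, beam)
        assert np.abs(np.abs(f_plus) - np.abs(f_minus)).max() > 0.1

    def test_point_group_orbit_has_equal_amplitudes(self, cell, beam):
        for seed in (1, 5, 9):
            model = generate_toy_structure(25, cell, seed=seed)
            orbit = np.array(
                [[3, 5, 7], [3, -5, -7], [-3, 5, -7], [-3, -5, 7]]
            )
            f, _ = structure_factor(model, orbit, beam)
            np.testing.assert_allclose(
                np.abs(f), np.abs(f[0]), rtol=1e-10
            )

    def test_systematic_absences_are_exactly_zero(self, default_model, beam):
        axial = np.array([[3, 0, 0], [5, 0, 0], [0, 3, 0], [0, 0, 5]])
        f, _ = structure_factor(default_model, axial, beam)
        present, _ = structure_factor(default_model, np.array([[2, 0, 0]]), beam)
        assert np.abs(f).max() < 1e-9 * np.abs(present)[0]

    def test_single_atom_at_origin_identity_ops(self, cell, beam):
        """A lone scatterer at the origin gives the same F for every h."""
        identity = SymmetryOps(
            rotations=(((1, 0, 0), (0, 1, 0), (0, 0, 1)),),
            translations=((0.0, 0.0, 0.0),),
        )
        hkl = np.array([[1, 2, 3], [4, 0, 1], [-2, 5, -7]])
        fp, fm = structure_factor_direct(
            hkl,
            np.array([[0.0, 0.0, 0.0]]),
            np.array([5.0 + 2.0j]),
            np.array([1.0]),
            np.array([0.0]),
            cell,
            identity,
        )
        np.testing.assert_allclose(fp, 5.0 + 2.0j, rtol=1e-12)
        np.testing.assert_allclose(fp, fm, rtol=1e-12)  # zero Bijvoet difference


class TestSimulator:
    def test_noiseless_single_observation_reproduces_intensities(
        self, default_model, beam
    ):
        obs = simulate_unmerged(
            default_model, beam, 3.0, multiplicity=1, noise_frac=0.0,
            mu=1.54, path=0.165, seed=0,
        )
        refl = reflection_list(default_model.cell, 3.0)
        hkl = refl[["h", "k", "l"]].to_numpy()
        fp, _ = structure_factor(default_model, hkl, beam)
        t = physics.transmission(1.54, 0.165)
        plus = obs.iloc[: len(hkl)]
        np.testing.assert_allclose(
            plus["I"].to_numpy(), t * np.abs(fp) ** 2, rtol=1e-12
        )

    def test_same_seed_reproducible(self, default_model, beam):
        a = simulate_unmerged(default_model, beam, 3.0, seed=11)
        b = simulate_unmerged(default_model, beam, 3.0, seed=11)
        assert a.equals(b)

    def test_sigma_recorded_truthfully(self, default_model, beam):
        obs = simulate_unmerged(
            default_model, beam, 3.0, multiplicity=2, noise_frac=0.1, seed=2
        )
        assert (obs["sigma"] > 0).all()
        assert (obs["I"] > 0).all()  # negatives clamped

    def test_bijvoet_ratio_monotone_in_b_imag(self, cell, beam):
        """⟨|I⁺−I⁻|⟩/⟨I⟩ grows with the resonance strength of the site."""
        ratios = []
        for b_imag in (2.0, 5.0, 8.5):
            model = generate_toy_structure(
                200, cell, seed=6, b_imag_override=b_imag
            )
            refl = reflection_list(cell, 3.0)
            hkl = refl[["h", "k", "l"]].to_numpy()
            fp, fm = structure_factor(model, hkl, beam)
            ip, im = np.abs(fp) ** 2, np.abs(fm) ** 2
            ratios.append(np.abs(ip - im).mean() / ((ip + im) / 2).mean())
        assert ratios[0] < ratios[1] < ratios[2]

    def test_invalid_arguments_rejected(self, default_model, beam):
        with pytest.raises(ValueError):
            simulate_unmerged(default_model, beam, 3.0, multiplicity=0)
        with pytest.raises(ValueError):
            simulate_unmerged(default_model, beam, 3.0, noise_frac=-0.1)
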