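"""SAD phasing: substructure factors, phase estimation, maps, hand choice."""

import numpy as np
import pandas as pd
import pytest

from nsad import crystal, merging, phasing
from nsad.crystal import P212121, SymmetryOps, reflection_list, structure_factor
from nsad.patterson import Map3D
from nsad.phasing import (
    PhaseSet,
    centric_phase,
    choose_hand,
    fourier_map,
    heavy_atom_sf,
    invert_sites,
    map_cc,
    mean_phase_error,
    sad_phases,
    true_phase_set,
    wilson_scale,
)


def _phase_run(model, beam, noise_frac, seed, d_min=2.30):
    """Simulate, merge and phase with the true site (isolates the estimator)."""
    from nsad import physics

    cell = model.cell
    obs = crystal.simulate_unmerged(
        model, beam, d_min, multiplicity=13, noise_frac=noise_frac, seed=seed
    )
    merged = merging.merge(obs)
    b_imag = physics.breit_wigner(physics.get_isotope("Cd113"), beam).b_imag
    b_sub = complex(-8.0, b_imag)
    site = np.array(model.atoms[model.anomalous_site].xyz)
    hkl = merged[["h", "k", "l"]].to_numpy()
    sum_b_sq = model.protein_sum_b_sq()
    scale = wilson_scale(merged, cell, sum_b_sq + abs(b_sub) ** 2)
    cd_b = model.atoms[model.anomalous_site].b_iso
    fh_p, fh_m = heavy_atom_sf(site, hkl, b_sub, cell, b_iso=cd_b)
    return sad_phases(
        merged, fh_p, fh_m, cell, scale=scale, sum_b_sq_protein=sum_b_sq
    )


class TestHeavyAtomSF:
    def test_single_origin_site_identity_ops(self, cell):
        """One site at the origin with identity ops: F_H = b for every h."""
        identity = SymmetryOps(
            rotations=(((1, 0, 0), (0, 1, 0), (0, 0, 1)),),
            translations=((0.0, 0.0, 0.0),),
        )
        hkl = np.array([[1, 0, 0], [2, 3, 1], [-4, 1, 2]])
        fp, fm = heavy_atom_sf(
            np.array([[0.0, 0.0, 0.0]]), hkl, complex(-8, 8.5), cell, identity
        )
        np.testing.assert_allclose(fp, complex(-8, 8.5), rtol=1e-12)
        np.testing.assert_allclose(fm, complex(-8, 8.5), rtol=1e-12)

    def test_matches_direct_sum_oracle(self, cell):
        rng = np.random.default_rng(3)
        sites = rng.uniform(0, 1, (2, 3))
        hkl = rng.integers(-5, 6, (8, 3))
        b = complex(-8.0, 8.5)
        fp, fm = heavy_atom_sf(sites, hkl, b, cell, b_iso=7.0)
        for row, p, m in zip(hkl, fp, fm):
            d = cell.d_spacing(np.array([row]))[0]
            dw = np.exp(-7.0 / (4 * d * d))
            acc_p = acc_m = 0j
            for x in sites:
                for R, t in zip(P212121.R, P212121.t):
                    pos = R @ x + t
                    acc_p += b * dw * np.exp(2j * np.pi * np.dot(row, pos))
                    acc_m += b * dw * np.exp(-2j * np.pi * np.dot(row, pos))
            assert abs(p - acc_p) < 1e-10 * abs(acc_p)
            assert abs(m - acc_m) < 1e-10 * abs(acc_m)

    def test_conjugation_restored_without_absorption(self, cell):
        rng = np.random.default_rng(4)
        hkl = rng.integers(-4, 5, (10, 3))
        fp, fm = heavy_atom_sf(
            np.array([[0.3, 0.6, 0.1]]), hkl, complex(-8.0, 0.0), cell
        )
        np.testing.assert_allclose(fm, np.conj(fp), rtol=1e-12)

    def test_empty_sites_rejected(self, cell):
        with pytest.raises(ValueError):
            heavy_atom_sf(np.empty((0, 3)), np.array([[1, 2, 3]]), 1j, cell)


class TestCentricPhase:
    def test_zone_restrictions(self):
        """Centric phases follow φ = π·(h·t) for the op sending h → −h."""
        # (0,k,l): op4 t = (1/2,1/2,0) → φ0 = πk/2 mod π
        phi = centric_phase(np.array([[0, 2, 3], [0, 1, 4], [3, 0, 2], [2, 1, 0]]))
        assert phi[0] == pytest.approx((np.pi * 1.0) % np.pi)   # k=2 → π·1 ≡ 0
        assert phi[1] == pytest.approx(np.pi / 2)               # k=1 → π/2
        # (h,0,l): op3 t = (0,1/2,1/2) → φ0 = πl/2 mod π; l=2 → 0
        assert phi[2] == pytest.approx(0.0)
        # (h,k,0): op2 t = (1/2,0,1/2) → φ0 = πh/2 mod π; h=2 → 0
        assert phi[3] == pytest.approx(0.0)

    def test_acentric_returns_nan(self):
        assert np.isnan(centric_phase(np.array([[1, 2, 3]]))[0])

    def test_true_phases_satisfy_restriction(self, default_model, beam):
        """Simulated centric reflections obey their phase restriction."""
        refl = reflection_list(default_model.cell, 3.0)
        zone = refl[(refl[["h", "k", "l"]] == 0).any(axis=1)]
        hkl = zone[["h", "k", "l"]].to_numpy()
        # drop the anomalous contribution: restriction applies to real part
        model = crystal.generate_toy_structure(
            706, default_model.cell, seed=1, b_imag_override=0.0
        )
        f, _ = structure_factor(model, hkl, beam)
        phi0 = centric_phase(hkl)
        delta = np.angle(f * np.exp(-1j * phi0))
        # each phase is φ0 or φ0 + π
        assert np.all(
            (np.abs(delta) < 1e-6) | (np.abs(np.abs(delta) - np.pi) < 1e-6)
        )


class TestSADPhases:
    def test_noiseless_phase_error_within_ambiguity_limit(
        self, default_model, beam
    ):
        """Noiseless bisector phasing: weighted error near the theoretical
        Blow-Crick ambiguity bound (≈33°), far from random (90°)."""
        ps = _phase_run(default_model, beam, 0.0, seed=1)
        truth = true_phase_set(default_model, beam, 2.30)
        wmpe = mean_phase_error(ps, truth, weighted=True)
        assert wmpe < 40.0
        assert mean_phase_error(ps, truth, weighted=False) < 60.0

    def test_foms_bounded_and_phases_wrapped(self, default_model, beam):
        ps = _phase_run(default_model, beam, 0.28, seed=2)
        t = ps.table
        assert ((t["fom"] >= 0) & (t["fom"] <= 1)).all()
        assert ((t["phi"] >= 0) & (t["phi"] < 2 * np.pi)).all()

    def test_fom_decreases_with_noise(self, default_model, beam):
        """Three-level noise scan: mean figure of merit falls monotonically."""
        foms = [
            _phase_run(default_model, beam, nf, seed=3).table["fom"].mean()
            for nf in (0.05, 0.3, 0.9)
        ]
        assert foms[0] > foms[1] > foms[2]

    def test_wrong_hand_phases_worse(self, default_model, beam):
        """The inverted substructure yields a larger phase error."""
        from nsad import physics

        cell = default_model.cell
        obs = crystal.simulate_unmerged(
            default_model, beam, 2.30, multiplicity=13, noise_frac=0.28, seed=4
        )
        merged = merging.merge(obs)
        b_imag = physics.breit_wigner(physics.get_isotope("Cd113"), beam).b_imag
        b_sub = complex(-8.0, b_imag)
        site = np.array(default_model.atoms[0].xyz)
        hkl = merged[["h", "k", "l"]].to_numpy()
        sum_b_sq = default_model.protein_sum_b_sq()
        scale = wilson_scale(merged, cell, sum_b_sq + abs(b_sub) ** 2)
        cd_b = default_model.atoms[0].b_iso
        truth = true_phase_set(default_model, beam, 2.30)
        errs = {}
        for hand, s in (("original", site), ("inverted", invert_sites(site)[0])):
            fh_p, fh_m = heavy_atom_sf(s, hkl, b_sub, cell, b_iso=cd_b)
            ps = sad_phases(
                merged, fh_p, fh_m, cell, scale=scale,
                sum_b_sq_protein=sum_b_sq, hand=hand,
            )
            errs[hand] = mean_phase_error(ps, truth, weighted=True)
        assert errs["original"] < errs["inverted"]

    def test_zero_anomalous_vector_flagged(self, cell):
        """ΔF with a vanishing substructure handle falls back to the
        substructure phase with a low figure of merit."""
        merged = pd.DataFrame(
            {
                "h": [1], "k": [2], "l": [3],
                "I_plus": [100.0], "sigma_plus": [1.0], "n_plus": [2],
                "I_minus": [100.0], "sigma_minus": [1.0], "n_minus": [2],
                "centric": [False],
            }
        )
        ps = sad_phases(
            merged,
            np.array([0 + 0j]),
            np.array([0 + 0j]),
            cell,
            scale=np.array([1.0]),
            sum_b_sq_protein=1000.0,
        )
        assert ps.table["flagged"].iloc[0]
        assert ps.table["fom"].iloc[0] <= 0.1


class TestFourierMap:
    def test_fft_matches_direct_sum(self, cell):
        """Map synthesis equals the explicit symmetry-expanded direct sum."""
        rng = np.random.default_rng(7)
        hkl = np.array([[1, 2, 3], [2, 0, 1], [0, 2, 2], [3, 1, 1]])
        table = pd.DataFrame(
            {
                "h": hkl[:, 0], "k": hkl[:, 1], "l": hkl[:, 2],
                "F": rng.uniform(1, 5, 4),
                "phi": rng.uniform(0, 2 * np.pi, 4),
                "fom": 1.0,
            }
        )
        ps = PhaseSet(table=table, hand="test")
        m = fourier_map(ps, cell, grid=(8, 8, 8), d_min=0.1)
        xs = np.arange(8) / 8
        X, Y, Z = np.meshgrid(xs, xs, xs, indexing="ij")
        direct = np.zeros((8, 8, 8))
        placed = {}
        for row in table.itertuples(index=False):
            c0 = row.F * np.exp(1j * row.phi)
            h0 = np.array([row.h, row.k, row.l])
            for R, t in zip(P212121.R, P212121.t):
                h = h0 @ R
                c = c0 * np.exp(-2j * np.pi * (h0 @ t))
                placed[tuple(h % 8)] = c
                placed[tuple((-h) % 8)] = np.conj(c)
        for idx, c in placed.items():
            direct += (
                c * np.exp(-2j * np.pi * (idx[0] * X + idx[1] * Y + idx[2] * Z))
            ).real
        raw = m.values * m.raw_sigma + m.raw_mean
        np.testing.assert_allclose(raw, direct, atol=1e-9 * np.abs(direct).max())

    def test_true_map_peaks_at_atom_positions(self, cell, beam):
        """The map from true F and phases puts density on the atoms."""
        model = crystal.generate_toy_structure(40, cell, seed=6)
        truth = true_phase_set(model, beam, 2.0)
        m = fourier_map(truth, cell, d_min=2.0)
        map3d = Map3D(
            values=m.values, cell=cell, raw_mean=m.raw_mean, raw_sigma=m.raw_sigma
        )
        at_atoms = map3d.interpolate(model.xyz)
        assert at_atoms.mean() > 1.5  # well above the σ=1 background

    def test_zero_fom_map_rejected_as_flat(self, cell):
        table = pd.DataFrame(
            {
                "h": [1, 2], "k": [2, 0], "l": [3, 1],
                "F": [5.0, 3.0], "phi": [0.1, 1.2], "fom": [0.0, 0.0],
            }
        )
        with pytest.raises(ValueError, match="flat"):
            fourier_map(PhaseSet(table=table, hand="x"), cell, grid=(8, 8, 8), d_min=0.1)


class TestMapCC:
    def _map(self, values, cell):
        return Map3D(
            values=values, cell=cell, raw_mean=0.0, raw_sigma=1.0
        )

    def test_identity_and_negation(self, cell):
        rng = np.random.default_rng(0)
        v = rng.normal(0, 1, (6, 6, 6))
        m = self._map(v, cell)
        assert map_cc(m, m) == pytest.approx(1.0)
        assert map_cc(m, self._map(-v, cell)) == pytest.approx(-1.0)

    def test_matches_pearson_oracle(self, cell):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, (6, 6, 6)), rng.normal(0, 1, (6, 6, 6))
        expected = np.corrcoef(a.ravel(), b.ravel())[0, 1]
        assert map_cc(self._map(a, cell), self._map(b, cell)) == pytest.approx(
            expected
        )

    def test_grid_mismatch_rejected(self, cell):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError):
            map_cc(
                self._map(rng.normal(0, 1, (6, 6, 6)), cell),
                self._map(rng.normal(0, 1, (8, 8, 8)), cell),
            )


class TestChooseHand:
    def _map(self, values, cell):
        return Map3D(values=values, cell=cell, raw_mean=0.0, raw_sigma=1.0)

    def test_identical_maps_undecided(self, cell):
        rng = np.random.default_rng(3)
        v = rng.normal(0, 1, (8, 8, 8))
        assert choose_hand(self._map(v, cell), self._map(v.copy(), cell)).selected == "undecided"

    def test_negation_flips_decision(self, cell):
        rng = np.random.default_rng(4)
        v = rng.gamma(2.0, 1.0, (8, 8, 8))  # positively skewed
        a, b = self._map(v, cell), self._map(-v, cell)
        assert choose_hand(a, b).selected == "original"
        assert choose_hand(b, a).selected == "inverted"
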