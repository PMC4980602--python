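"""Find the anomalous scatterer from an anomalous-difference Patterson map.

Plants a Cd-like site at a known position, simulates noisy data, builds the
|ΔF|² Patterson, reads peaks off the three Harker sections of P2₁2₁2₁ and
inverts the Harker relations to recover the site — the desk-scale analogue
of a dual-space substructure search for the single-site case.
"""

import numpy as np

from nsad import crystal, merging, patterson, physics

cell = crystal.RUBREDOXIN_CELL
beam = physics.energy_from_wavelength(1.17)
true_site = (0.137, 0.260, 0.411)

model = crystal.generate_toy_structure(706, cell, seed=4)
atoms = list(model.atoms)
atoms[0] = crystal.Atom(isotope=atoms[0].isotope, xyz=true_site,
                        b_iso=atoms[0].b_iso)
model = crystal.CrystalModel(cell=cell, ops=model.ops, atoms=tuple(atoms),
                             anomalous_site=0, seed=4)

obs = crystal.simulate_unmerged(model, beam, 2.3, multiplicity=13,
                                noise_frac=0.28, seed=4)
merged = merging.merge(obs)
coeffs = patterson.anomalous_differences(merged)
pmap = patterson.patterson_map(coeffs, cell, d_min=2.3)

peaks = patterson.harker_peaks(pmap, top_n=1, sigma_cut=3.0)
for name, plist in peaks.items():
    for p in plist:
        print(f"Harker section {name} = 1/2: peak at "
              f"({p.uvw[0]:.3f}, {p.uvw[1]:.3f}), {p.height_sigma:.1f} sigma")
print("  (the study's neutron map showed the same signature at 9.0 sigma)")

sols = patterson.solve_site_from_harker(peaks, pmap, min_score=4.5,
                                        coeffs=coeffs)
best = sols[0]
err = patterson.min_site_distance(best.xyz, true_site, cell)
print(f"\nbest site (canonical): ({best.xyz[0]:.4f}, {best.xyz[1]:.4f}, "
      f"{best.xyz[2]:.4f}), consistency {best.score:.1f} sigma")
print(f"distance to planted site (mod origin/hand): {err:.3f} A")
print("  (sites are defined only up to the normalizer ambiguities of P212121)")
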