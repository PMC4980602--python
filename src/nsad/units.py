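"""Unit conventions and conversion constants.

The package works in a single, fixed unit system:

* energy in meV,
* lengths and d-spacings in Å,
* scattering lengths in fm,
* cross sections in barn,
* linear attenuation coefficients in cm⁻¹.

All conversions funnel through the constants below so that unit handling
is exact (powers of ten) and testable.
"""

from __future__ import annotations

#: de Broglie constant: E[meV] = DEBROGLIE_MEV_A2 / λ[Å]².
DEBROGLIE_MEV_A2: float = 81.804

#: 1 fm = 1e-5 Å.
FM_PER_ANGSTROM: float = 1e5
ANGSTROM_PER_FM: float = 1e-5

#: 1 barn = 1e-24 cm² = 1e-8 Å².
BARN_PER_ANGSTROM2: float = 1e8
ANGSTROM2_PER_BARN: float = 1e-8

#: barn/Å³ → cm⁻¹ : (1e-24 cm²) / (1e-24 cm³) = 1.
#: A cross-section sum in barn divided by a cell volume in Å³ is already cm⁻¹.
CM_INV_PER_BARN_PER_A3: float = 1.0

#: Reference wavelength of the 2200 m/s thermal convention (Å); tabulated
#: absorption cross sections refer to this wavelength and scale ∝ λ.
THERMAL_LAMBDA: float = 1.798


def fm_to_angstrom(b_fm: float) -> float:
    return b_fm * ANGSTROM_PER_FM


def angstrom_to_fm(b_a: float) -> float:
    return b_a * FM_PER_ANGSTROM


def barn_to_angstrom2(sigma_barn: float) -> float:
    return sigma_barn * ANGSTROM2_PER_BARN


def angstrom2_to_barn(sigma_a2: float) -> float:
    return sigma_a2 * BARN_PER_ANGSTROM2
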