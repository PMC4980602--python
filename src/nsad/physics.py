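"""Wavelength-dependent neutron resonance scattering and feasibility estimates.

Near a nuclear resonance the neutron scattering length becomes complex,

    b(E) = R + g · Γₙ(E)/(2k) · 1/((E − E_r) − iΓ/2),

the single-level Breit-Wigner form with potential-scattering term ``R``,
resonance energy ``E_r``, total width ``Γ``, neutron re-emission width
``Γₙ`` (∝ √E for s-wave capture, referenced at ``E_r``) and spin
statistical factor ``g = (2J+1)/(2(2I+1))``.  The sign convention is
``b = b′ + i·b″`` with ``b″ ≥ 0`` for an absorber, so that the total
removal cross section follows the optical theorem, ``σ = 4π·b″/k``.

For ¹¹³Cd the 178 meV resonance makes ``b″`` comparable in magnitude to
ordinary coherent scattering lengths at thermal wavelengths, which is what
makes neutron SAD phasing on a Cd-substituted protein practical.  The module
also provides the linear attenuation coefficient of a crystal (summed
absorption + incoherent cross sections per cell volume), beam transmission,
and the rule-of-thumb Bijvoet signal estimate

    ΔF/F ≈ √2 · (√N_a · Δb″) / (√N_p · b_av),

which is independent of scattering angle because nuclei scatter as points.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from . import units

__all__ = [
    "NeutronBeam",
    "ResonanceParams",
    "IsotopeEntry",
    "ComplexScatteringLength",
    "CompositionEntry",
    "FeasibilityInput",
    "energy_from_wavelength",
    "wavelength_from_energy",
    "breit_wigner",
    "cross_section_from_b_imag",
    "sigma_abs_at_wavelength",
    "attenuation_coefficient",
    "transmission",
    "anomalous_signal_estimate",
    "isotope_table",
    "get_isotope",
    "build_composition",
    "RUBREDOXIN_PROTEIN_COUNTS",
    "rubredoxin_cell_composition",
]


# --------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class NeutronBeam:
    """A monochromatic beam: wavelength (Å), energy (meV), wavenumber (Å⁻¹).

    The three fields are mutually consistent: E = 81.804/λ², k = 2π/λ.
    Construct via :func:`energy_from_wavelength`.
    """

    wavelength: float
    energy: float
    k: float

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError(f"wavelength must be > 0, got {self.wavelength}")
        e = units.DEBROGLIE_MEV_A2 / self.wavelength**2
        if not (
            math.isclose(self.energy, e, rel_tol=1e-9)
            and math.isclose(self.k, 2 * math.pi / self.wavelength, rel_tol=1e-9)
        ):
            raise ValueError("inconsistent (wavelength, energy, k) triple")


@dataclass(frozen=True)
class ResonanceParams:
    """Single-level resonance: E_r, Γ, Γₙ in meV; potential radius R in fm.

    ``g`` is the spin statistical factor (2J+1)/(2(2I+1)); compilations often
    tabulate gΓₙ instead of Γₙ, so it is kept explicit here.
    """

    E_r: float
    Gamma: float
    Gamma_n: float
    R: float
    g: float = 1.0

    def __post_init__(self) -> None:
        if self.E_r <= 0:
            raise ValueError("E_r must be > 0")
        if not (self.Gamma >= self.Gamma_n > 0):
            raise ValueError("require Gamma >= Gamma_n > 0")
        if self.R <= 0:
            raise ValueError("R must be > 0")
        if not 0 < self.g <= 1:
            raise ValueError("g must be in (0, 1]")


@dataclass(frozen=True)
class IsotopeEntry:
    """One row of the isotope table.

    ``b_coh_far`` is the real coherent scattering length far from any
    resonance (fm); for resonant nuclei it doubles as the potential
    scattering term of the Breit-Wigner expression.  ``sigma_abs_thermal``
    is the 2200 m/s absorption cross section (barn) used for 1/v absorbers
    without tabulated resonances.
    """

    label: str
    b_coh_far: float
    sigma_inc: float
    resonances: tuple[ResonanceParams, ...] = ()
    sigma_abs_thermal: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_inc < 0:
            raise ValueError("sigma_inc must be >= 0")
        if self.sigma_abs_thermal < 0:
            raise ValueError("sigma_abs_thermal must be >= 0")


@dataclass(frozen=True)
class ComplexScatteringLength:
    """b = b′ + i·b″ (fm) at a given wavelength; b″ ≥ 0 for absorbers."""

    b_real: float
    b_imag: float
    at_wavelength: float

    def __post_init__(self) -> None:
        if self.b_imag < -1e-12:
            raise ValueError("b_imag must be >= 0 under the b = b' + i b'' convention")

    @property
    def value(self) -> complex:
        return complex(self.b_real, self.b_imag)


@dataclass(frozen=True)
class CompositionEntry:
    """An isotope with its count per unit cell and σ_abs(λ) in barn."""

    isotope: IsotopeEntry
    count_per_cell: float
    sigma_abs_at_lambda: float

    def __post_init__(self) -> None:
        if self.count_per_cell < 0 or self.sigma_abs_at_lambda < 0:
            raise ValueError("counts and cross sections must be non-negative")


@dataclass(frozen=True)
class FeasibilityInput:
    """Inputs of the √2·(√N_a·Δb″)/(√N_p·b_av) Bijvoet-signal estimate."""

    N_a: float
    N_p: float
    b_av: float
    delta_b_imag: float

    def __post_init__(self) -> None:
        if min(self.N_a, self.N_p, self.b_av) <= 0:
            raise ValueError("N_a, N_p and b_av must be strictly positive")
        if self.delta_b_imag < 0:
            raise ValueError("delta_b_imag must be >= 0")
        if self.N_a > self.N_p:
            raise ValueError("N_a must not exceed N_p")


# --------------------------------------------------------------------------
# beam construction


def energy_from_wavelength(wavelength: float) -> NeutronBeam:
    """Build a consistent (λ, E, k) triple from λ in Å."""
    if wavelength <= 0:
        raise ValueError(f"wavelength must be > 0, got {wavelength}")
    return NeutronBeam(
        wavelength=wavelength,
        energy=units.DEBROGLIE_MEV_A2 / wavelength**2,
        k=2 * math.pi / wavelength,
    )


def wavelength_from_energy(energy_mev: float) -> NeutronBeam:
    """Build a beam from E in meV (inverse of :func:`energy_from_wavelength`)."""
    if energy_mev <= 0:
        raise ValueError("energy must be > 0")
    return energy_from_wavelength(math.sqrt(units.DEBROGLIE_MEV_A2 / energy_mev))


# --------------------------------------------------------------------------
# resonance scattering


def breit_wigner(iso: IsotopeEntry, beam: NeutronBeam) -> ComplexScatteringLength:
    """Complex scattering length of ``iso`` at the beam wavelength.

    Sums the single-level Breit-Wigner term over all listed resonances, with
    the s-wave energy dependence Γₙ(E) = Γₙ·√(E/E_r).  An isotope without
    resonances returns (b_coh_far, 0) with a warning.
    """
    if not iso.resonances:
        warnings.warn(
            f"{iso.label}: no resonances tabulated; returning far-field value",
            stacklevel=2,
        )
        return ComplexScatteringLength(iso.b_coh_far, 0.0, beam.wavelength)

    E, k = beam.energy, beam.k
    b = complex(iso.b_coh_far, 0.0)  # fm
    for res in iso.resonances:
        gamma_n_e = res.Gamma_n * math.sqrt(E / res.E_r)
        # term in Å, converted to fm below
        term = (res.g * gamma_n_e / (2 * k)) / complex(E - res.E_r, -res.Gamma / 2)
        b += term * units.FM_PER_ANGSTROM
    return ComplexScatteringLength(b.real, b.imag, beam.wavelength)


def cross_section_from_b_imag(b_imag: float, beam: NeutronBeam) -> float:
    """Optical-theorem cross section σ = 4π·b″/k, in barn (b″ in fm)."""
    if b_imag < 0:
        raise ValueError("b_imag must be >= 0")
    sigma_a2 = 4 * math.pi * (b_imag * units.ANGSTROM_PER_FM) / beam.k
    return units.angstrom2_to_barn(sigma_a2)


def sigma_abs_at_wavelength(iso: IsotopeEntry, beam: NeutronBeam) -> float:
    """Absorption cross section (barn) at λ: resonant via Breit-Wigner,
    otherwise 1/v scaling of the 2200 m/s value."""
    if iso.resonances:
        return cross_section_from_b_imag(breit_wigner(iso, beam).b_imag, beam)
    return iso.sigma_abs_thermal * beam.wavelength / units.THERMAL_LAMBDA


# --------------------------------------------------------------------------
# attenuation


def attenuation_coefficient(
    composition: list[CompositionEntry] | tuple[CompositionEntry, ...],
    cell_volume: float,
) -> float:
    """Linear attenuation coefficient μ (cm⁻¹).

    μ = Σ_atoms (σ_abs(λ) + σ_inc) / V; a cross-section sum in barn divided
    by a volume in Å³ is numerically cm⁻¹ (10⁻²⁴ cm² per barn cancels
    10⁻²⁴ cm³ per Å³).
    """
    if cell_volume <= 0:
        raise ValueError("cell_volume must be > 0")
    if not composition:
        warnings.warn("empty composition: mu = 0", stacklevel=2)
        return 0.0
    total_barn = sum(
        c.count_per_cell * (c.sigma_abs_at_lambda + c.isotope.sigma_inc)
        for c in composition
    )
    return total_barn / cell_volume * units.CM_INV_PER_BARN_PER_A3


def transmission(mu: float, path: float) -> float:
    """Beam transmission T = exp(−μ·path); μ in cm⁻¹, path in cm."""
    if mu < 0 or path < 0:
        raise ValueError("mu and path must be >= 0")
    return math.exp(-mu * path)


# --------------------------------------------------------------------------
# feasibility


def anomalous_signal_estimate(inp: FeasibilityInput) -> float:
    """Expected Bijvoet amplitude signal ΔF/F ≈ √2·(√N_a·Δb″)/(√N_p·b_av).

    Dimensionless fraction, independent of scattering angle.
    """
    denom = math.sqrt(inp.N_p) * inp.b_av
    if denom == 0:
        raise ValueError("zero denominator")
    return math.sqrt(2.0) * math.sqrt(inp.N_a) * inp.delta_b_imag / denom


# --------------------------------------------------------------------------
# shipped isotope table


def isotope_table() -> dict[str, IsotopeEntry]:
    """Load the versioned isotope CSV shipped with the package."""
    with resources.files("nsad.data").joinpath("isotopes.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    table: dict[str, IsotopeEntry] = {}
    for label, rows in df.groupby("label", sort=False):
        first = rows.iloc[0]
        res = []
        for _, r in rows.iterrows():
            if np.isfinite(r.get("E_r_meV", np.nan)):
                res.append(
                    ResonanceParams(
                        E_r=float(r["E_r_meV"]),
                        Gamma=float(r["Gamma_meV"]),
                        Gamma_n=float(r["Gamma_n_meV"]),
                        R=float(first["b_coh_far"]),
                        g=float(r["g"]),
                    )
                )
        if label in table:
            raise ValueError(f"duplicate isotope label {label!r}")
        table[str(label)] = IsotopeEntry(
            label=str(label),
            b_coh_far=float(first["b_coh_far"]),
            sigma_inc=float(first["sigma_inc"]),
            resonances=tuple(res),
            sigma_abs_thermal=float(first["sigma_abs_thermal"]),
        )
    return table


def get_isotope(label: str) -> IsotopeEntry:
    table = isotope_table()
    try:
        return table[label]
    except KeyError:
        raise KeyError(
            f"unknown isotope {label!r}; available: {sorted(table)}"
        ) from None


# --------------------------------------------------------------------------
# reference composition (54-residue perdeuterated rubredoxin-like protein)

#: Atom counts per asymmetric unit for the toy perdeuterated protein
#: (54 residues, all H replaced by D): 705 atoms.
RUBREDOXIN_PROTEIN_COUNTS: dict[str, int] = {
    "C": 226,
    "D": 352,
    "N": 60,
    "O": 62,
    "S": 5,
}

#: Ordered D₂O molecules per asymmetric unit in the reference cell.
RUBREDOXIN_N_WATERS: int = 49


def build_composition(
    counts: dict[str, float], beam: NeutronBeam
) -> list[CompositionEntry]:
    """Turn {isotope label: count per cell} into CompositionEntry list."""
    table = isotope_table()
    return [
        CompositionEntry(
            isotope=table[label],
            count_per_cell=n,
            sigma_abs_at_lambda=sigma_abs_at_wavelength(table[label], beam),
        )
        for label, n in counts.items()
    ]


def rubredoxin_cell_composition(
    beam: NeutronBeam, z: int = 4, include_solvent: bool = True
) -> list[CompositionEntry]:
    """Unit-cell composition of the reference crystal for attenuation.

    ``z`` copies (P2₁2₁2₁ has 4) of the 705-atom perdeuterated protein plus
    one ¹¹³Cd each; optionally 49 ordered D₂O per asymmetric unit.
    """
    counts = {k: float(z * v) for k, v in RUBREDOXIN_PROTEIN_COUNTS.items()}
    if include_solvent:
        counts["D"] += z * 2 * RUBREDOXIN_N_WATERS
        counts["O"] += z * RUBREDOXIN_N_WATERS
    counts["Cd113"] = float(z)
    return build_composition(counts, beam)
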