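"""Synthetic perdeuterated-protein crystal and Friedel-pair diffraction simulator.

The generator emulates the study system: an orthorhombic P2₁2₁2₁ crystal
(space group #19, four symmetry copies per cell) holding a compact globular
cluster of perdeuterated protein-like atoms (C, D, N, O, S with their
coherent scattering lengths) plus a single ¹¹³Cd-like anomalous scatterer
whose real scattering length is −8.0 fm and whose imaginary part b″ comes
from the Breit-Wigner resonance at the simulation wavelength.

Structure factors are the standard crystallographic sums

    F(h) = Σ_ops Σ_atoms occ · b · exp(2πi h·(Rx + t)) · exp(−B s²/4),

with s = 1/d.  Because the anomalous site has b″ > 0, Friedel's law breaks:
F(−h) ≠ conj(F(h)), which is the signal every downstream stage consumes.
Intensity observations are simulated per reflection and Friedel sign with a
chosen multiplicity, Gaussian noise σ = noise_frac·I + floor, and a single
mean-path transmission factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import physics
from .physics import IsotopeEntry, NeutronBeam

__all__ = [
    "UnitCell",
    "SymmetryOps",
    "P212121",
    "Atom",
    "CrystalModel",
    "ReflectionObs",
    "CD_B_REAL_FM",
    "generate_toy_structure",
    "reflection_list",
    "structure_factor",
    "structure_factor_direct",
    "simulate_unmerged",
    "RUBREDOXIN_CELL",
]

#: Real coherent scattering length adopted for the ¹¹³Cd site (fm).
CD_B_REAL_FM: float = -8.0


@dataclass(frozen=True)
class UnitCell:
    """Orthorhombic cell: a, b, c in Å, all angles 90°."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be > 0")

    @property
    def volume(self) -> float:
        return self.a * self.b * self.c

    def d_spacing(self, hkl: np.ndarray) -> np.ndarray:
        """d (Å) for an (n, 3) integer array of Miller indices."""
        hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
        inv_d2 = (
            (hkl[:, 0] / self.a) ** 2
            + (hkl[:, 1] / self.b) ** 2
            + (hkl[:, 2] / self.c) ** 2
        )
        with np.errstate(divide="ignore"):
            return 1.0 / np.sqrt(inv_d2)

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        """Fractional → cartesian Å (diagonal for orthorhombic)."""
        return np.asarray(frac, dtype=float) * np.array([self.a, self.b, self.c])


#: Cell of the reference crystal (Å).
RUBREDOXIN_CELL = UnitCell(34.44, 35.14, 43.78)


@dataclass(frozen=True)
class SymmetryOps:
    """Rotation+translation pairs in fractional coordinates."""

    rotations: tuple  # of 3x3 int tuples
    translations: tuple  # of 3-tuples

    def __post_init__(self) -> None:
        if len(self.rotations) != len(self.translations):
            raise ValueError("rotations and translations must pair up")

    def __len__(self) -> int:
        return len(self.rotations)

    @property
    def R(self) -> np.ndarray:
        """(n_ops, 3, 3) integer rotation parts."""
        return np.array(self.rotations, dtype=int)

    @property
    def t(self) -> np.ndarray:
        """(n_ops, 3) translation parts."""
        return np.array(self.translations, dtype=float)

    def apply(self, frac: np.ndarray) -> np.ndarray:
        """All images of fractional coordinates: (n_ops, n_atoms, 3), mod 1."""
        x = np.atleast_2d(frac)
        return (np.einsum("oij,aj->oai", self.R, x) + self.t[:, None, :]) % 1.0

    def is_closed(self) -> bool:
        """Closure under composition modulo lattice translations."""
        ops = list(zip(self.R, self.t))
        key = lambda R, t: (tuple(R.ravel()), tuple(np.round(np.mod(t, 1.0), 6)))
        have = {key(R, t) for R, t in ops}
        for R1, t1 in ops:
            for R2, t2 in ops:
                if key(R1 @ R2, R1 @ t2 + t1) not in have:
                    return False
        return True


#: The four operators of P2₁2₁2₁ (ITA #19 standard setting).
P212121 = SymmetryOps(
    rotations=(
        ((1, 0, 0), (0, 1, 0), (0, 0, 1)),
        ((-1, 0, 0), (0, -1, 0), (0, 0, 1)),
        ((-1, 0, 0), (0, 1, 0), (0, 0, -1)),
        ((1, 0, 0), (0, -1, 0), (0, 0, -1)),
    ),
    translations=(
        (0.0, 0.0, 0.0),
        (0.5, 0.0, 0.5),
        (0.0, 0.5, 0.5),
        (0.5, 0.5, 0.0),
    ),
)


@dataclass(frozen=True)
class Atom:
    isotope: IsotopeEntry
    xyz: tuple  # fractional, each in [0, 1)
    occupancy: float = 1.0
    b_iso: float = 10.0  # isotropic displacement B (Å²)

    def __post_init__(self) -> None:
        if not all(0.0 <= u < 1.0 for u in self.xyz):
            raise ValueError("fractional coordinates must be in [0, 1)")
        if not 0.0 < self.occupancy <= 1.0:
            raise ValueError("occupancy must be in (0, 1]")
        if self.b_iso < 0:
            raise ValueError("B must be >= 0")


@dataclass(frozen=True)
class CrystalModel:
    """Ground truth of a simulation: cell, symmetry, asymmetric-unit atoms.

    Exactly one atom (``anomalous_site``) is the Cd-like anomalous
    scatterer; all others scatter with their real coherent lengths only.
    """

    cell: UnitCell
    ops: SymmetryOps
    atoms: tuple  # of Atom
    anomalous_site: int
    seed: int
    b_imag_override: float | None = None  # force b″ (fm), e.g. 0 for controls

    def __post_init__(self) -> None:
        if not 0 <= self.anomalous_site < len(self.atoms):
            raise ValueError("anomalous_site out of range")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def xyz(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    @property
    def b_iso(self) -> np.ndarray:
        return np.array([a.b_iso for a in self.atoms], dtype=float)

    @property
    def occupancy(self) -> np.ndarray:
        return np.array([a.occupancy for a in self.atoms], dtype=float)

    def scattering_lengths(self, beam: NeutronBeam) -> np.ndarray:
        """Complex b (fm) per atom at the beam wavelength.

        Protein atoms use their real coherent lengths; the anomalous site
        uses b′ = −8.0 fm with b″ from the Breit-Wigner resonance.
        """
        b = np.array([a.isotope.b_coh_far for a in self.atoms], dtype=complex)
        cd = self.atoms[self.anomalous_site]
        if self.b_imag_override is not None:
            b_imag = self.b_imag_override
        elif cd.isotope.resonances:
            b_imag = physics.breit_wigner(cd.isotope, beam).b_imag
        else:
            b_imag = 0.0
        b[self.anomalous_site] = complex(CD_B_REAL_FM, b_imag)
        return b

    def protein_sum_b_sq(self) -> float:
        """Σ b² over non-anomalous atoms (fm²), the Wilson/Sim variance scale."""
        return float(
            sum(
                a.isotope.b_coh_far**2
                for i, a in enumerate(self.atoms)
                if i != self.anomalous_site
            )
        )


@dataclass(frozen=True)
class ReflectionObs:
    """A single unmerged intensity observation."""

    hkl: tuple
    I: float
    sigma: float
    batch: int

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


# --------------------------------------------------------------------------
# model generation


def generate_toy_structure(
    n_atoms: int,
    cell: UnitCell = RUBREDOXIN_CELL,
    seed: int = 0,
    *,
    blob_sigma: float = 7.0,
    anomalous_isotope: str = "Cd113",
    b_imag_override: float | None = None,
) -> CrystalModel:
    """Reproducible toy model: n_atoms−1 protein atoms plus one anomalous site.

    Protein atoms are drawn from the perdeuterated palette (C, D, N, O, S)
    with rubredoxin-like frequencies at pseudo-random positions with a
    compact globular bias (a Gaussian blob of width ``blob_sigma`` Å around
    a random centre); B-factors are uniform in [5, 20] Å².  The same seed
    yields an identical model.
    """
    if n_atoms < 2:
        raise ValueError("n_atoms must be >= 2 (need protein + anomalous atom)")
    rng = np.random.default_rng(seed)
    table = physics.isotope_table()
    palette = list(physics.RUBREDOXIN_PROTEIN_COUNTS)
    weights = np.array(
        [physics.RUBREDOXIN_PROTEIN_COUNTS[k] for k in palette], dtype=float
    )
    weights /= weights.sum()

    centre = rng.uniform(0.1, 0.4, size=3)  # keep the blob off special positions
    axes = np.array([cell.a, cell.b, cell.c])

    labels = rng.choice(palette, size=n_atoms - 1, p=weights)
    offsets = rng.normal(0.0, blob_sigma, size=(n_atoms, 3)) / axes
    frac = (centre + offsets) % 1.0
    b_isos = rng.uniform(5.0, 20.0, size=n_atoms)

    atoms = [
        Atom(
            isotope=table[anomalous_isotope],
            xyz=tuple(frac[0]),
            b_iso=float(b_isos[0]),
        )
    ]
    atoms += [
        Atom(isotope=table[lab], xyz=tuple(frac[i + 1]), b_iso=float(b_isos[i + 1]))
        for i, lab in enumerate(labels)
    ]
    return CrystalModel(
        cell=cell,
        ops=P212121,
        atoms=tuple(atoms),
        anomalous_site=0,
        seed=seed,
        b_imag_override=b_imag_override,
    )


# --------------------------------------------------------------------------
# reflection enumeration


def reflection_list(
    cell: UnitCell, d_min: float, ops: SymmetryOps = P212121
) -> pd.DataFrame:
    """Unique reflections of the mmm asymmetric unit (h, k, l ≥ 0) to d_min.

    Systematic absences of the three 2₁ screw axes (odd axial h00/0k0/00l)
    are excluded.  Each row represents the reflection and its Friedel mate
    (−h, −k, −l).  Returns a DataFrame with columns h, k, l, d.
    """
    if d_min <= 0:
        raise ValueError("d_min must be > 0")
    hmax = int(cell.a // d_min) + 1
    kmax = int(cell.b // d_min) + 1
    lmax = int(cell.c // d_min) + 1
    h, k, l = np.meshgrid(
        np.arange(hmax + 1), np.arange(kmax + 1), np.arange(lmax + 1), indexing="ij"
    )
    hkl = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
    hkl = hkl[np.any(hkl != 0, axis=1)]
    d = cell.d_spacing(hkl)
    keep = d >= d_min
    hkl, d = hkl[keep], d[keep]

    # 2_1 screw absences: axial reflections with odd index
    axial = (hkl != 0).sum(axis=1) == 1
    odd = hkl.sum(axis=1) % 2 == 1
    keep = ~(axial & odd)
    hkl, d = hkl[keep], d[keep]

    if len(hkl) == 0:
        warnings.warn("no reflections inside the resolution limit", stacklevel=2)
    out = pd.DataFrame({"h": hkl[:, 0], "k": hkl[:, 1], "l": hkl[:, 2], "d": d})
    return out.sort_values("d", ascending=False, ignore_index=True)


# --------------------------------------------------------------------------
# structure factors


def structure_factor_direct(
    hkl: np.ndarray,
    xyz: np.ndarray,
    b_complex: np.ndarray,
    occupancy: np.ndarray,
    b_iso: np.ndarray,
    cell: UnitCell,
    ops: SymmetryOps,
) -> tuple[np.ndarray, np.ndarray]:
    """F(h) and F(−h) for arbitrary atoms; the workhorse behind both the
    simulator and the substructure calculation.

    Returns complex arrays in fm (per unit cell).  F(−h) is evaluated
    explicitly — no conjugation shortcut — so complex b is handled exactly.
    """
    hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
    xyz = np.atleast_2d(xyz)
    d = cell.d_spacing(hkl)
    s2_over4 = 1.0 / (4.0 * d**2)  # (sinθ/λ)² = s²/4 with s = 1/d
    dw = np.exp(-np.outer(s2_over4, np.asarray(b_iso, dtype=float)))  # (nref, natom)
    w = dw * (np.asarray(occupancy, dtype=float) * 1.0)[None, :]

    f_plus = np.zeros(len(hkl), dtype=complex)
    f_minus = np.zeros(len(hkl), dtype=complex)
    b = np.asarray(b_complex, dtype=complex)
    for R, t in zip(ops.R, ops.t):
        pos = xyz @ R.T + t  # (natom, 3)
        phase = np.exp(2j * np.pi * (hkl @ pos.T))  # (nref, natom)
        f_plus += (phase * w) @ b
        f_minus += (np.conj(phase) * w) @ b
    return f_plus, f_minus


def structure_factor(
    model: CrystalModel, hkl: np.ndarray, beam: NeutronBeam
) -> tuple[np.ndarray, np.ndarray]:
    """F(h), F(−h) of the full model at the beam wavelength (fm)."""
    return structure_factor_direct(
        hkl,
        model.xyz,
        model.scattering_lengths(beam),
        model.occupancy,
        model.b_iso,
        model.cell,
        model.ops,
    )


# --------------------------------------------------------------------------
# intensity simulation


def simulate_unmerged(
    model: CrystalModel,
    beam: NeutronBeam,
    d_min: float,
    multiplicity: int = 13,
    noise_frac: float = 0.28,
    mu: float = 0.0,
    path: float = 0.0,
    seed: int = 0,
    *,
    noise_floor_frac: float = 0.02,
) -> pd.DataFrame:
    """Simulate unmerged Friedel-pair observations.

    Per unique reflection and Friedel sign, ``multiplicity`` observations of
    I = T·|F|² (T = exp(−μ·path)) perturbed with Gaussian noise of
    σ = noise_frac·I + floor, where the floor is ``noise_floor_frac`` times
    the median noiseless intensity.  σ values are stored truthfully; noisy
    intensities that land below zero are clamped to a small positive epsilon
    with σ kept.  Columns: h, k, l (signed), I, sigma, batch.
    """
    if multiplicity < 1:
        raise ValueError("multiplicity must be >= 1")
    if noise_frac < 0:
        raise ValueError("noise_frac must be >= 0")
    refl = reflection_list(model.cell, d_min, model.ops)
    hkl = refl[["h", "k", "l"]].to_numpy()
    f_plus, f_minus = structure_factor(model, hkl, beam)
    t_factor = physics.transmission(mu, path)

    i_true = np.concatenate(
        [t_factor * np.abs(f_plus) ** 2, t_factor * np.abs(f_minus) ** 2]
    )
    hkl_signed = np.vstack([hkl, -hkl])
    floor = noise_floor_frac * np.median(i_true)

    rng = np.random.default_rng(seed)
    n = len(i_true)
    i_rep = np.repeat(i_true, multiplicity)
    if noise_frac == 0.0:
        # exactly noiseless: intensities reproduce T·|F|²
        i_obs = i_rep.copy()
        sigma = np.full_like(i_rep, 1e-12)
    else:
        sigma = noise_frac * i_rep + floor
        i_obs = rng.normal(i_rep, sigma)
    eps = 1e-9 * max(float(np.median(i_true)), 1.0)
    i_obs = np.maximum(i_obs, eps)

    out = pd.DataFrame(
        {
            "h": np.repeat(hkl_signed[:, 0], multiplicity),
            "k": np.repeat(hkl_signed[:, 1], multiplicity),
            "l": np.repeat(hkl_signed[:, 2], multiplicity),
            "I": i_obs,
            "sigma": np.maximum(sigma, 1e-12),
            "batch": np.tile(np.arange(multiplicity), n),
        }
    )
    out.attrs["d_min"] = d_min
    out.attrs["transmission"] = t_factor
    return out
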