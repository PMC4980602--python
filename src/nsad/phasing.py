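"""SAD phase estimation from Bijvoet pairs and a located substructure.

Writing the total structure factor as F(h) = G(h) + H(h), where G collects
all *real* scattering (Friedel-even, G(−h) = conj G(h)) and H = i·b″·S(h)
is the imaginary substructure part, the two measured Bijvoet amplitudes
constrain G to the intersection of two circles,

    |G + H| = |F⁺|,       |G − H| = |F⁻|,

the single-wavelength Harker construction.  The intersection leaves a
two-fold ambiguity which is resolved statistically:

* acentric reflections: Sim-style weighting of the two candidates toward
  the known real substructure contribution K = b′·S(h) (the unknown
  protein part is a 2-D random walk of variance ε = n_ops·Σb²·DW²);
* centric zone reflections (h, k or l = 0 in 222): the protein phase is
  symmetry-restricted to φ₀/φ₀+π, which resolves the ambiguity outright.

The phase estimate is the weighted centroid of the two candidates; the
figure of merit is the centroid length (cosine of half the ambiguity for
equal weights) damped by the anomalous signal-to-noise of the reflection.
No density modification of any kind is applied — hand discrimination uses
only the map statistics (skewness) of the two candidate maps, an automated
stand-in for visual inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .crystal import (
    P212121,
    CrystalModel,
    NeutronBeam,
    SymmetryOps,
    UnitCell,
    structure_factor,
    structure_factor_direct,
)
from .merging import assign_shells, canonical_index, shell_edges
from .patterson import Map3D, _normalize

__all__ = [
    "PhaseSet",
    "HandChoice",
    "heavy_atom_sf",
    "wilson_scale",
    "fit_substructure",
    "sad_phases",
    "fourier_map",
    "map_cc",
    "choose_hand",
    "true_phase_set",
    "mean_phase_error",
    "invert_sites",
]


@dataclass(frozen=True)
class PhaseSet:
    """Phases for one substructure hand: a table with per-reflection
    amplitude |F| (fm scale), phase φ in [0, 2π) and figure of merit m."""

    table: pd.DataFrame
    hand: str

    def __post_init__(self) -> None:
        if not {"h", "k", "l", "F", "phi", "fom"} <= set(self.table.columns):
            raise ValueError("phase table missing required columns")
        if ((self.table["fom"] < -1e-9) | (self.table["fom"] > 1 + 1e-9)).any():
            raise ValueError("figures of merit must lie in [0, 1]")
        if ((self.table["phi"] < 0) | (self.table["phi"] >= 2 * np.pi)).any():
            raise ValueError("phases must lie in [0, 2π)")


@dataclass(frozen=True)
class HandChoice:
    selected: str  # 'original' | 'inverted' | 'undecided'
    skew_original: float
    skew_inverted: float


def invert_sites(sites: np.ndarray) -> np.ndarray:
    """The enantiomorph substructure: (x, y, z) → (−x, −y, −z) mod 1."""
    return (-np.atleast_2d(np.asarray(sites, dtype=float))) % 1.0


# --------------------------------------------------------------------------
# substructure structure factors


def heavy_atom_sf(
    sites: np.ndarray,
    hkl: np.ndarray,
    b_sub: complex,
    cell: UnitCell,
    ops: SymmetryOps = P212121,
    *,
    b_iso: float = 0.0,
    occupancy: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """F_H(h), F_H(−h) of the substructure with the full complex b (fm).

    F_H(−h) is evaluated explicitly (no conjugation shortcut) so the
    imaginary part of b is carried correctly.
    """
    sites = np.atleast_2d(np.asarray(sites, dtype=float))
    if len(sites) == 0:
        raise ValueError("need at least one substructure site")
    n = len(sites)
    return structure_factor_direct(
        hkl,
        sites,
        np.full(n, b_sub, dtype=complex),
        np.full(n, occupancy),
        np.full(n, b_iso),
        cell,
        ops,
    )


# --------------------------------------------------------------------------
# scaling


def wilson_scale(
    merged: pd.DataFrame,
    cell: UnitCell,
    sum_b_sq: float,
    *,
    n_ops: int = 4,
    mean_b_iso: float = 12.5,
    n_bins: int = 10,
) -> np.ndarray:
    """Per-reflection factor k putting √I on the absolute |F| scale (fm).

    Shell-wise: k = √(⟨|F|²⟩_expected / ⟨I⟩_shell) with the Wilson
    expectation ⟨|F|²⟩ = n_ops·Σ|b|²·exp(−B̄ s²/2).
    """
    d = cell.d_spacing(merged[["h", "k", "l"]].to_numpy())
    i_pair = np.nanmean(
        np.column_stack([merged["I_plus"].to_numpy(), merged["I_minus"].to_numpy()]),
        axis=1,
    )
    edges = shell_edges(float(d.max()) + 1e-6, float(d.min()) - 1e-9, n_bins)
    shell = assign_shells(d, edges)
    k = np.empty(len(merged))
    for i in range(n_bins):
        sel = shell == i
        if not sel.any():
            continue
        s2 = 1.0 / d[sel] ** 2
        target = n_ops * sum_b_sq * np.exp(-mean_b_iso * s2.mean() / 2.0)
        mean_i = float(np.nanmean(i_pair[sel]))
        k[sel] = np.sqrt(target / max(mean_i, 1e-30))
    return k


def fit_substructure(
    dF: np.ndarray, h_mag0: np.ndarray, d: np.ndarray, *, n_bins: int = 8
) -> tuple[float, float]:
    """Fit occupancy-like scale c and displacement B of the substructure.

    For a single anomalous site ⟨|ΔF|⟩ = (4/π)·|H| with H the imaginary
    substructure vector; regressing shell means of
    log(⟨|ΔF|⟩ / ((4/π)·⟨|H₀|⟩)) on s²/4 gives −B as slope and log c as
    intercept.  ``h_mag0`` is |H| computed with B = 0, occupancy 1.
    """
    edges = shell_edges(float(d.max()) + 1e-6, float(d.min()) - 1e-9, n_bins)
    shell = assign_shells(d, edges)
    xs, ys = [], []
    for i in range(n_bins):
        sel = shell == i
        if sel.sum() < 5:
            continue
        mean_df = float(np.abs(dF[sel]).mean())
        mean_h = float(h_mag0[sel].mean())
        if mean_df <= 0 or mean_h <= 0:
            continue
        xs.append(float((1.0 / (4.0 * d[sel] ** 2)).mean()))
        ys.append(np.log(mean_df / ((4.0 / np.pi) * mean_h)))
    if len(xs) < 2:
        return 1.0, 10.0
    slope, intercept = np.polyfit(xs, ys, 1)
    b_fit = float(np.clip(-slope, 0.0, 60.0))
    c_fit = float(np.clip(np.exp(intercept), 1e-3, 1e3))
    return c_fit, b_fit


# --------------------------------------------------------------------------
# centric phase restrictions

# reciprocal sign patterns of the 222 point ops, aligned with P212121 ops
_RECIP_PATTERNS = np.array(
    [[1, 1, 1], [-1, -1, 1], [-1, 1, -1], [1, -1, -1]], dtype=int
)


def centric_phase(hkl: np.ndarray, ops: SymmetryOps = P212121) -> np.ndarray:
    """Symmetry-restricted protein phase φ₀ ∈ [0, π) for centric reflections.

    For the op with hR = −h, conj(F) = F·exp(−2πi h·t) forces
    φ = π·(h·t) mod π.  Non-centric rows return NaN.
    """
    hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
    out = np.full(len(hkl), np.nan)
    t = ops.t
    for j in range(1, len(_RECIP_PATTERNS)):
        maps_to_minus = np.all(hkl * _RECIP_PATTERNS[j] == -hkl, axis=1)
        phi0 = (np.pi * (hkl @ t[j])) % np.pi
        out = np.where(maps_to_minus & np.isnan(out), phi0, out)
    return out


# --------------------------------------------------------------------------
# the SAD phase estimator


def sad_phases(
    merged: pd.DataFrame,
    fh_plus: np.ndarray,
    fh_minus: np.ndarray,
    cell: UnitCell,
    *,
    scale: np.ndarray,
    sum_b_sq_protein: float,
    n_ops: int = 4,
    mean_b_iso: float = 12.5,
    hand: str = "original",
) -> PhaseSet:
    """Estimate protein phases for one substructure hand.

    ``fh_plus``/``fh_minus`` are the substructure structure factors aligned
    with the rows of ``merged`` (already carrying any fitted substructure
    scale/B); ``scale`` puts √I on the same absolute scale.  Returns a
    :class:`PhaseSet` whose phases refer to the total structure factor
    F(h), suitable for direct map synthesis.
    """
    m = merged.reset_index(drop=True)
    hkl = m[["h", "k", "l"]].to_numpy()
    d = cell.d_spacing(hkl)
    s2 = 1.0 / d**2
    eps = n_ops * sum_b_sq_protein * np.exp(-mean_b_iso * s2 / 2.0)
    scale = np.asarray(scale, dtype=float)

    fh_p = np.asarray(fh_plus, dtype=complex)
    fh_m = np.asarray(fh_minus, dtype=complex)
    h_vec = (fh_p - np.conj(fh_m)) / 2.0  # i·b″·S(h)
    k_vec = (fh_p + np.conj(fh_m)) / 2.0  # b′·S(h)

    centric = (
        m["centric"].to_numpy() if "centric" in m else np.zeros(len(m), bool)
    )
    n_plus = m["n_plus"].to_numpy()
    n_minus = m["n_minus"].to_numpy()
    ip = np.maximum(np.nan_to_num(m["I_plus"].to_numpy()), 0.0)
    im = np.maximum(np.nan_to_num(m["I_minus"].to_numpy()), 0.0)
    sp = np.nan_to_num(m["sigma_plus"].to_numpy(), nan=np.inf)
    sm = np.nan_to_num(m["sigma_minus"].to_numpy(), nan=np.inf)

    fp = scale * np.sqrt(ip)
    fm = scale * np.sqrt(im)
    phi = np.zeros(len(m))
    fom = np.zeros(len(m))
    amp = np.zeros(len(m))
    flagged = np.zeros(len(m), dtype=bool)

    # --- centric zone reflections: phase restricted to φ0 / φ0+π ---------
    cen = centric & (n_plus > 0)
    if cen.any():
        phi0 = centric_phase(hkl[cen])
        f_amp = fp[cen]
        e0 = np.exp(1j * phi0)
        # centric Wilson prior: variance 2ε along the restricted line
        lw1 = -np.abs(f_amp * e0 - k_vec[cen]) ** 2 / (2.0 * eps[cen])
        lw2 = -np.abs(-f_amp * e0 - k_vec[cen]) ** 2 / (2.0 * eps[cen])
        mx = np.maximum(lw1, lw2)
        w1, w2 = np.exp(lw1 - mx), np.exp(lw2 - mx)
        z = (w1 * e0 - w2 * e0) / (w1 + w2)
        with np.errstate(divide="ignore", invalid="ignore"):
            snr = np.where(
                (f_amp > 0) & (sp[cen] > 0),
                f_amp / (scale[cen] * sp[cen] / (2.0 * np.sqrt(np.maximum(ip[cen], 1e-30)))),
                np.inf,
            )
        damp = np.where(np.isinf(snr), 1.0, snr / (1.0 + snr))
        phi[cen] = np.angle(z) % (2 * np.pi)
        fom[cen] = np.minimum(1.0, np.abs(z) * damp)
        amp[cen] = f_amp

    # --- acentric Bijvoet-complete reflections ---------------------------
    ace = ~centric & (n_plus > 0) & (n_minus > 0)
    if ace.any():
        hh = h_vec[ace]
        kk = k_vec[ace]
        fpa, fma = fp[ace], fm[ace]
        h_mag = np.abs(hh)
        deg = h_mag < 1e-10  # no anomalous handle at all
        h_safe = np.where(deg, 1.0, h_mag)
        u_hat = hh / h_safe
        dd = 2.0 * h_mag
        a = np.where(deg, 0.0, (dd**2 + fpa**2 - fma**2) / np.where(deg, 1.0, 2.0 * dd))
        h2 = fpa**2 - a**2
        infeasible = (h2 < 0.0) & ~deg
        hgt = np.sqrt(np.maximum(h2, 0.0))
        base = -hh + a * u_hat
        g1 = base + 1j * u_hat * hgt
        g2 = base - 1j * u_hat * hgt
        f1 = g1 + hh
        f2 = g2 + hh
        lw1 = -np.abs(g1 - kk) ** 2 / eps[ace]
        lw2 = -np.abs(g2 - kk) ** 2 / eps[ace]
        mx = np.maximum(lw1, lw2)
        w1, w2 = np.exp(lw1 - mx), np.exp(lw2 - mx)
        with np.errstate(invalid="ignore"):
            z = (
                w1 * np.exp(1j * np.angle(f1)) + w2 * np.exp(1j * np.angle(f2))
            ) / (w1 + w2)

        sig_df = scale[ace] * np.sqrt(
            (sp[ace] / (2.0 * np.sqrt(np.maximum(ip[ace], 1e-30)))) ** 2
            + (sm[ace] / (2.0 * np.sqrt(np.maximum(im[ace], 1e-30)))) ** 2
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.where(sig_df > 0, dd / sig_df, np.inf)
        damp = np.where(np.isinf(q), 1.0, q / (1.0 + q))

        phi_a = np.angle(z) % (2 * np.pi)
        fom_a = np.minimum(1.0, np.abs(z) * damp)
        fom_a = np.where(infeasible, 0.3 * fom_a, fom_a)
        # degenerate: phase from the real substructure part alone, low FOM
        phi_a = np.where(deg, np.angle(kk) % (2 * np.pi), phi_a)
        fom_a = np.where(deg, 0.05, fom_a)

        phi[ace] = phi_a
        fom[ace] = fom_a
        amp[ace] = (fpa + fma) / 2.0
        flagged[ace] = infeasible | deg

    usable = cen | ace
    phi = np.where(phi >= 2 * np.pi, 0.0, phi)  # guard float wrap at 2π
    table = pd.DataFrame(
        {
            "h": hkl[usable, 0],
            "k": hkl[usable, 1],
            "l": hkl[usable, 2],
            "F": amp[usable],
            "phi": phi[usable],
            "fom": np.clip(np.nan_to_num(fom[usable]), 0.0, 1.0),
            "centric": centric[usable],
            "flagged": flagged[usable],
        }
    )
    return PhaseSet(table=table, hand=hand)


# --------------------------------------------------------------------------
# map synthesis and comparison


def fourier_map(
    phase_set: PhaseSet,
    cell: UnitCell,
    grid: tuple[int, int, int] | None = None,
    *,
    ops: SymmetryOps = P212121,
    d_min: float = 2.30,
    use_fom: bool = True,
) -> Map3D:
    """FFT synthesis of the m·|F|·exp(iφ) map, normalized to mean 0, σ 1.

    Coefficients are expanded over the space-group operators
    (F(hR) = F(h)·exp(−2πi h·t)) with Hermitian mates, so the map is real.
    Reflections beyond ``d_min`` are excluded (2.30 Å default for the
    experimental map).
    """
    from .patterson import grid_for_cell

    t = phase_set.table
    d = cell.d_spacing(t[["h", "k", "l"]].to_numpy())
    sel = d >= d_min
    if not sel.any():
        raise ValueError("no reflections at or below the map resolution")
    hkl = t[["h", "k", "l"]].to_numpy()[sel]
    amp = t["F"].to_numpy()[sel] * (t["fom"].to_numpy()[sel] if use_fom else 1.0)
    coeff = amp * np.exp(1j * t["phi"].to_numpy()[sel])

    if grid is None:
        grid = grid_for_cell(cell, d_min)
    dims = np.array(grid)
    f = np.zeros(grid, dtype=complex)
    for R, tr in zip(ops.R, ops.t):
        h_img = hkl @ R  # row-vector transform
        c_img = coeff * np.exp(-2j * np.pi * (hkl @ tr))
        idx = h_img % dims
        f[idx[:, 0], idx[:, 1], idx[:, 2]] = c_img
        idx_m = (-h_img) % dims
        f[idx_m[:, 0], idx_m[:, 1], idx_m[:, 2]] = np.conj(c_img)
    values = np.fft.fftn(f).real
    if float(values.std()) <= 0:
        raise ValueError("flat map (all figures of merit zero?)")
    return _normalize(values, cell, 0.0)


def map_cc(map_a: Map3D, map_b: Map3D) -> float:
    """Pearson correlation of two maps over grid points (same grid/cell)."""
    if map_a.shape != map_b.shape:
        raise ValueError("maps must share a grid")
    a, b = map_a.values.ravel(), map_b.values.ravel()
    if a.std() == 0 or b.std() == 0:
        raise ValueError("cannot correlate a flat map")
    return float(np.corrcoef(a, b)[0, 1])


def choose_hand(
    map_original: Map3D, map_inverted: Map3D, *, tie_threshold: float = 1e-4
) -> HandChoice:
    """Pick the hand whose map has the larger skewness.

    A correctly phased scattering-length density is sharply peaked and
    positively skewed (an automated proxy for visual inspection); the wrong
    hand yields a flatter, more symmetric map.  'Undecided' is reserved for
    genuinely degenerate cases — e.g. a site on a special position, where
    the two hands describe the same substructure and the maps are isometric
    (skew difference at numerical-noise level, below ``tie_threshold``);
    real maps separate by 10⁻²–10⁻¹.
    """
    s_orig = float(stats.skew(map_original.values.ravel()))
    s_inv = float(stats.skew(map_inverted.values.ravel()))
    if abs(s_orig - s_inv) < tie_threshold:
        return HandChoice("undecided", s_orig, s_inv)
    return HandChoice(
        "original" if s_orig > s_inv else "inverted", s_orig, s_inv
    )


# --------------------------------------------------------------------------
# synthetic-mode truth references


def true_phase_set(
    model: CrystalModel, beam: NeutronBeam, d_min: float
) -> PhaseSet:
    """Ground-truth amplitudes and phases of the simulated crystal (fom 1)."""
    from .crystal import reflection_list

    refl = reflection_list(model.cell, d_min, model.ops)
    hkl = refl[["h", "k", "l"]].to_numpy()
    f_plus, _ = structure_factor(model, hkl, beam)
    phi = np.angle(f_plus) % (2 * np.pi)
    phi = np.where(phi >= 2 * np.pi, 0.0, phi)
    table = pd.DataFrame(
        {
            "h": hkl[:, 0],
            "k": hkl[:, 1],
            "l": hkl[:, 2],
            "F": np.abs(f_plus),
            "phi": phi,
            "fom": 1.0,
        }
    )
    return PhaseSet(table=table, hand="truth")


def mean_phase_error(
    estimated: PhaseSet, truth: PhaseSet, *, weighted: bool = True
) -> float:
    """Mean absolute phase difference in degrees, FOM-weighted by default
    (the standard weighted mean phase error of experimental phasing)."""
    a = estimated.table.set_index(["h", "k", "l"])
    b = truth.table.set_index(["h", "k", "l"])
    joined = a.join(b, how="inner", lsuffix="_est", rsuffix="_true")
    if len(joined) == 0:
        raise ValueError("no common reflections")
    delta = np.angle(np.exp(1j * (joined["phi_est"] - joined["phi_true"])))
    err = np.abs(delta)
    if weighted:
        w = joined["fom_est"].to_numpy()
        return float(np.degrees((err * w).sum() / max(w.sum(), 1e-30)))
    return float(np.degrees(err.mean()))
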