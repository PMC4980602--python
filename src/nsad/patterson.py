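"""Anomalous-difference Patterson synthesis and single-site back-solving.

The anomalous-difference Patterson

    P(u) = Σ_h |ΔF(h)|² cos(2π h·u),     ΔF = √I⁺ − √I⁻,

is real and centrosymmetric, and peaks at interatomic vectors between
anomalous scatterers.  In P2₁2₁2₁ the self-vectors of a site (x, y, z)
concentrate on three Harker sections:

    w = ½ :  (2x − ½, 2y)
    v = ½ :  (2x, 2z − ½)
    u = ½ :  (2y − ½, 2z)

so a single site can be recovered by reading peaks off the sections and
inverting these relations, enumerating the ± (centrosymmetry of the map)
and half-cell origin ambiguities and scoring every candidate by how well
its predicted Harker vectors land on actual map density.  Solutions are
canonicalized to the fundamental domain 0 ≤ x, y, z ≤ ¼ of the Euclidean
normalizer (independent half-cell origin shifts and sign flips per axis),
which makes recovery well defined.

Maps are σ-scaled: normalized to mean 0 and σ 1 with a small region around
the (always dominant) origin peak excluded from the statistics, so peak
heights are reported in the σ units used in practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crystal import UnitCell

__all__ = [
    "Map3D",
    "Peak",
    "SiteSolution",
    "anomalous_differences",
    "grid_for_cell",
    "patterson_map",
    "harker_sections",
    "find_peaks_2d",
    "peak_search",
    "harker_peaks",
    "solve_site_from_harker",
    "harker_score",
    "refine_site",
    "canonical_site",
    "site_images",
    "min_site_distance",
    "align_site",
]


@dataclass
class Map3D:
    """A map on a fractional grid with σ-scaling metadata.

    ``values`` are stored in σ units (mean 0, σ 1 over the unmasked
    region); ``raw_mean``/``raw_sigma`` record the normalization.
    """

    values: np.ndarray
    cell: UnitCell
    raw_mean: float
    raw_sigma: float
    origin_mask_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("map grid must be 3-D with dims >= 2")
        if self.raw_sigma <= 0:
            raise ValueError("map sigma must be > 0 after normalization")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def interpolate(self, frac: np.ndarray) -> np.ndarray:
        """Periodic trilinear interpolation at fractional coordinates."""
        frac = np.atleast_2d(np.asarray(frac, dtype=float)) % 1.0
        dims = np.array(self.shape)
        g = frac * dims
        i0 = np.floor(g).astype(int)
        frac_part = g - i0
        out = np.zeros(len(frac))
        for corner in range(8):
            off = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
            idx = (i0 + off) % dims
            w = np.prod(
                np.where(off == 1, frac_part, 1.0 - frac_part), axis=1
            )
            out += w * self.values[idx[:, 0], idx[:, 1], idx[:, 2]]
        return out


@dataclass(frozen=True)
class Peak:
    """A local map maximum; height in σ units of the parent map."""

    uvw: tuple
    height_sigma: float
    section: str = "general"  # 'u', 'v', 'w' Harker plane or 'general'


@dataclass(frozen=True)
class SiteSolution:
    """A candidate anomalous site in the canonical fundamental domain."""

    xyz: tuple
    score: float
    origin_choice: tuple = (0, 0, 0)
    hand: str = "original"

    def __post_init__(self) -> None:
        if not all(0.0 <= u <= 0.25 + 1e-9 for u in self.xyz):
            raise ValueError("canonical site must lie in [0, 1/4]^3")


# --------------------------------------------------------------------------
# coefficients


def anomalous_differences(
    merged: pd.DataFrame, *, snr_cut: float = 0.0
) -> pd.DataFrame:
    """Bijvoet amplitude differences ΔF = √I⁺ − √I⁻ with propagated σ.

    Works on Bijvoet-complete acentric rows of a merged table; non-positive
    intensities are clamped to zero amplitude.  Reflections with
    |ΔF|/σ(ΔF) below ``snr_cut`` are down-weighted via a ``weight`` column
    (1 by default).
    """
    pairs = merged[(merged["n_plus"] > 0) & (merged["n_minus"] > 0)]
    if "centric" in merged:
        pairs = pairs[~pairs["centric"]]
    if len(pairs) == 0:
        raise ValueError("no complete Bijvoet pairs")
    ip = np.maximum(pairs["I_plus"].to_numpy(), 0.0)
    im = np.maximum(pairs["I_minus"].to_numpy(), 0.0)
    fp, fm = np.sqrt(ip), np.sqrt(im)
    with np.errstate(divide="ignore"):
        sp = np.where(fp > 0, pairs["sigma_plus"] / (2 * fp), np.inf)
        sm = np.where(fm > 0, pairs["sigma_minus"] / (2 * fm), np.inf)
    out = pd.DataFrame(
        {
            "h": pairs["h"].to_numpy(),
            "k": pairs["k"].to_numpy(),
            "l": pairs["l"].to_numpy(),
            "dF": fp - fm,
            "sigma_dF": np.sqrt(sp**2 + sm**2),
        }
    )
    snr = np.abs(out["dF"]) / np.where(out["sigma_dF"] > 0, out["sigma_dF"], np.inf)
    out["weight"] = np.where(snr >= snr_cut, 1.0, 0.0) if snr_cut > 0 else 1.0
    return out


# --------------------------------------------------------------------------
# map synthesis


def grid_for_cell(
    cell: UnitCell, d_min: float, spacing_factor: float = 3.0
) -> tuple[int, int, int]:
    """Even grid dims sampling the cell at d_min/spacing_factor (default /3),
    rounded up so the half-integer Harker planes are exact grid planes."""
    step = d_min / spacing_factor
    dims = []
    for length in (cell.a, cell.b, cell.c):
        n = int(math.ceil(length / step))
        dims.append(n + n % 2)
    return tuple(dims)  # type: ignore[return-value]


def _origin_mask(dims: tuple[int, int, int], radius_steps: float) -> np.ndarray:
    """Boolean mask of grid points within ``radius_steps`` grid steps of the
    origin (periodic)."""
    grids = np.meshgrid(
        *[np.minimum(np.arange(n), n - np.arange(n)) for n in dims], indexing="ij"
    )
    r2 = sum(g.astype(float) ** 2 for g in grids)
    return r2 <= radius_steps**2


def _normalize(values: np.ndarray, cell: UnitCell, mask_radius_steps: float) -> Map3D:
    mask = (
        _origin_mask(values.shape, mask_radius_steps)
        if mask_radius_steps > 0
        else np.zeros(values.shape, dtype=bool)
    )
    body = values[~mask]
    mean, sigma = float(body.mean()), float(body.std())
    if sigma <= 0:
        raise ValueError("degenerate (flat) map")
    return Map3D(
        values=(values - mean) / sigma,
        cell=cell,
        raw_mean=mean,
        raw_sigma=sigma,
        origin_mask_frac=mask_radius_steps / max(values.shape),
    )


def patterson_map(
    coeffs: pd.DataFrame,
    cell: UnitCell,
    grid: tuple[int, int, int] | None = None,
    *,
    d_min: float | None = None,
    origin_mask_steps: float = 1.5,
    weighted: bool = False,
) -> Map3D:
    """FFT synthesis of P(u) = Σ_h |ΔF|² cos(2π h·u), σ-scaled.

    ``coeffs`` is the output of :func:`anomalous_differences` (unique asu
    reflections); coefficients are expanded to the full mmm-symmetric set
    before the transform, so the map carries the Patterson symmetry of
    P2₁2₁2₁ exactly.  With ``weighted`` the optional 1/σ² down-weighting
    of uncertain differences is applied.
    """
    if len(coeffs) < 10:
        raise ValueError("need at least 10 coefficients")
    if grid is None:
        if d_min is None:
            d_min = float(
                cell.d_spacing(coeffs[["h", "k", "l"]].to_numpy()).min()
            )
        grid = grid_for_cell(cell, d_min)
    if any(n % 2 for n in grid):
        raise ValueError("grid dims must be even so Harker planes are exact")

    c = (coeffs["dF"].to_numpy() ** 2) * coeffs.get(
        "weight", pd.Series(1.0, index=coeffs.index)
    ).to_numpy()
    if weighted:
        with np.errstate(divide="ignore"):
            c = c / np.maximum(coeffs["sigma_dF"].to_numpy(), 1e-12) ** 2
    hkl = coeffs[["h", "k", "l"]].to_numpy()

    f = np.zeros(grid, dtype=complex)
    dims = np.array(grid)
    for sh in (1, -1):
        for sk in (1, -1):
            for sl in (1, -1):
                idx = (hkl * np.array([sh, sk, sl])) % dims
                f[idx[:, 0], idx[:, 1], idx[:, 2]] = c
    # ρ(x) = Σ_h F(h) e^{−2πi h·x} is numpy's forward FFT convention
    values = np.fft.fftn(f).real
    return _normalize(values, cell, origin_mask_steps)


def harker_sections(pmap: Map3D) -> dict[str, np.ndarray]:
    """The three Harker planes u=½, v=½, w=½ as 2-D arrays of σ-heights.

    Section axes: 'u' → (v, w); 'v' → (u, w); 'w' → (u, v).  Grid dims must
    be even so the planes are exact (enforced at map construction).
    """
    nx, ny, nz = pmap.shape
    if nx % 2 or ny % 2 or nz % 2:
        raise ValueError("Harker sections require even grid dims")
    return {
        "u": pmap.values[nx // 2, :, :].copy(),
        "v": pmap.values[:, ny // 2, :].copy(),
        "w": pmap.values[:, :, nz // 2].copy(),
    }


# --------------------------------------------------------------------------
# peak search


def _quadratic_offset(fm: float, f0: float, fp: float) -> float:
    denom = fm - 2 * f0 + fp
    if denom >= -1e-12:
        return 0.0
    return float(np.clip(0.5 * (fm - fp) / denom, -0.5, 0.5))


def find_peaks_2d(
    section: np.ndarray,
    top_n: int = 5,
    sigma_cut: float = 2.0,
    *,
    exclude: np.ndarray | None = None,
) -> list[tuple[float, float, float]]:
    """Local maxima of a periodic 2-D section above ``sigma_cut``.

    Returns (frac_i, frac_j, height) refined by quadratic interpolation
    over the 3×3 neighbourhood, sorted by height (descending).
    """
    from scipy.ndimage import maximum_filter

    local_max = section >= maximum_filter(section, size=3, mode="wrap")
    cand = local_max & (section >= sigma_cut)
    if exclude is not None:
        cand &= ~exclude
    peaks = []
    ni, nj = section.shape
    for i, j in zip(*np.nonzero(cand)):
        f0 = section[i, j]
        di = _quadratic_offset(
            section[(i - 1) % ni, j], f0, section[(i + 1) % ni, j]
        )
        dj = _quadratic_offset(
            section[i, (j - 1) % nj], f0, section[i, (j + 1) % nj]
        )
        peaks.append((((i + di) / ni) % 1.0, ((j + dj) / nj) % 1.0, float(f0)))
    peaks.sort(key=lambda p: -p[2])
    return peaks[:top_n]


def peak_search(
    pmap: Map3D,
    top_n: int = 10,
    sigma_cut: float = 2.0,
    *,
    origin_mask_steps: float = 1.5,
) -> list[Peak]:
    """Local maxima of a 3-D σ-scaled map, origin-masked, refined and sorted."""
    from scipy.ndimage import maximum_filter

    v = pmap.values
    local_max = v >= maximum_filter(v, size=3, mode="wrap")
    cand = local_max & (v >= sigma_cut) & ~_origin_mask(v.shape, origin_mask_steps)
    dims = v.shape
    peaks = []
    for i, j, kk in zip(*np.nonzero(cand)):
        f0 = v[i, j, kk]
        di = _quadratic_offset(v[(i - 1) % dims[0], j, kk], f0, v[(i + 1) % dims[0], j, kk])
        dj = _quadratic_offset(v[i, (j - 1) % dims[1], kk], f0, v[i, (j + 1) % dims[1], kk])
        dk = _quadratic_offset(v[i, j, (kk - 1) % dims[2]], f0, v[i, j, (kk + 1) % dims[2]])
        peaks.append(
            Peak(
                uvw=(
                    ((i + di) / dims[0]) % 1.0,
                    ((j + dj) / dims[1]) % 1.0,
                    ((kk + dk) / dims[2]) % 1.0,
                ),
                height_sigma=float(f0),
                section="general",
            )
        )
    peaks.sort(key=lambda p: -p.height_sigma)
    return peaks[:top_n]


def harker_peaks(
    pmap: Map3D, top_n: int = 3, sigma_cut: float = 2.0
) -> dict[str, list[Peak]]:
    """Peaks on each Harker section, origin images masked on the sections."""
    sections = harker_sections(pmap)
    dims = pmap.shape
    out: dict[str, list[Peak]] = {}
    for name, (sec, plane_dims) in {
        "u": (sections["u"], (dims[1], dims[2])),
        "v": (sections["v"], (dims[0], dims[2])),
        "w": (sections["w"], (dims[0], dims[1])),
    }.items():
        raw = find_peaks_2d(sec, top_n=top_n, sigma_cut=sigma_cut)
        out[name] = [
            Peak(uvw=(p[0], p[1]), height_sigma=p[2], section=name) for p in raw
        ]
    return out


# --------------------------------------------------------------------------
# site solving


def site_images(xyz: np.ndarray | tuple) -> np.ndarray:
    """All 64 equivalent descriptions of a single-site substructure.

    The Euclidean normalizer of P2₁2₁2₁ combines the space-group rotations,
    inversion (hand) and half-cell origin shifts; for a single site this
    works out to an *independent* sign flip and ½-shift along each axis:
    x → ±x + {0, ½} per axis, mod 1.
    """
    x = np.asarray(xyz, dtype=float)
    images = []
    for signs in np.ndindex(2, 2, 2):
        s = 1.0 - 2.0 * np.array(signs)
        base = (s * x) % 1.0
        for shift in np.ndindex(2, 2, 2):
            images.append((base + 0.5 * np.array(shift)) % 1.0)
    return np.array(images)


def canonical_site(xyz: np.ndarray | tuple) -> tuple[float, float, float]:
    """Canonical representative in the fundamental domain [0, ¼]³.

    Per axis the normalizer images of coordinate x are {±x + k/2}; reducing
    mod ½ and folding the sign leaves min(u, ½−u) with u = x mod ½.
    """
    x = np.asarray(xyz, dtype=float)
    u = x % 0.5
    return tuple(np.round(np.minimum(u, 0.5 - u), 12))  # type: ignore[return-value]


def min_site_distance(a, b, cell: UnitCell) -> float:
    """Minimum cartesian distance (Å) between site ``a`` and any normalizer
    image (origin/hand/symmetry) of site ``b``, with periodic wrapping."""
    a = np.asarray(a, dtype=float)
    best = np.inf
    for img in site_images(b):
        delta = (a - img + 0.5) % 1.0 - 0.5
        dist = np.linalg.norm(cell.orthogonalize(delta))
        best = min(best, float(dist))
    return best


def align_site(site, reference, cell: UnitCell) -> np.ndarray:
    """Gauge fixing for synthetic validation: the normalizer image of
    ``site`` closest (cartesian, periodic) to ``reference``.

    A single-site substructure is only defined up to the normalizer
    ambiguities, so any image phases equally well; picking the one nearest
    the known true site puts maps on a common origin/hand for comparison.
    """
    ref = np.asarray(reference, dtype=float)
    images = site_images(site)
    deltas = (images - ref + 0.5) % 1.0 - 0.5
    dists = np.linalg.norm(deltas * np.array([cell.a, cell.b, cell.c]), axis=1)
    return images[int(np.argmin(dists))]


def solve_site_from_harker(
    peaks: dict[str, list[Peak]],
    pmap: Map3D,
    *,
    min_score: float = 2.0,
    max_candidates: int = 10,
    coeffs: pd.DataFrame | None = None,
    ops=None,
) -> list[SiteSolution]:
    """Invert the P2₁2₁2₁ Harker relations for a single site.

    (x, y) candidates come from w=½ peaks via u = 2x−½, v = 2y and z
    candidates from v=½ peaks via w = 2z−½, enumerating the map
    centrosymmetry (±peak) and the half-cell ambiguity of dividing by two.
    Every candidate is scored by the mean interpolated σ-height of its three
    predicted Harker vectors; candidates below ``min_score`` are dropped.
    Returns canonicalized, deduplicated solutions, best first.
    """
    w_peaks = peaks.get("w", [])
    v_peaks = peaks.get("v", [])
    u_peaks = peaks.get("u", [])
    n_sections = sum(1 for p in (w_peaks, v_peaks, u_peaks) if p)
    if n_sections < 2:
        return []

    def halves(val: float) -> list[float]:
        # invert coord = 2x (mod 1): two x solutions half a cell apart
        return [(val / 2.0) % 1.0, (val / 2.0 + 0.5) % 1.0]

    # per-axis candidate values; each section peak contributes through the
    # Harker relations, with the centrosymmetric mate (±peak) enumerated
    x_cands: set[float] = set()
    y_cands: set[float] = set()
    z_cands: set[float] = set()
    for p in w_peaks:  # (2x−½, 2y)
        for s in (1.0, -1.0):
            x_cands.update(halves(s * p.uvw[0] + 0.5))
            y_cands.update(halves(s * p.uvw[1]))
    for p in v_peaks:  # (2x, 2z−½)
        for s in (1.0, -1.0):
            x_cands.update(halves(s * p.uvw[0]))
            z_cands.update(halves(s * p.uvw[1] + 0.5))
    for p in u_peaks:  # (2y−½, 2z)
        for s in (1.0, -1.0):
            y_cands.update(halves(s * p.uvw[0] + 0.5))
            z_cands.update(halves(s * p.uvw[1]))
    if not (x_cands and y_cands and z_cands):
        return []

    sites = np.array(
        [(x, y, z) for x in sorted(x_cands) for y in sorted(y_cands) for z in sorted(z_cands)]
    )
    score = harker_score(sites, pmap)

    solutions: dict[tuple, tuple] = {}
    for site, sc in zip(sites, score):
        if sc < min_score:
            continue
        canon = canonical_site(site)
        key = tuple(np.round(canon, 6))
        if key not in solutions or sc > solutions[key][1]:
            solutions[key] = (canon, float(sc))
    # optionally refine the best few against the anomalous differences,
    # then re-canonicalize, rescore on the map and dedupe
    shortlist = sorted(solutions.values(), key=lambda t: (-round(t[1], 9), t[0]))
    refined: dict[tuple, SiteSolution] = {}
    for canon, sc in shortlist[: 2 * max_candidates]:
        xyz = np.asarray(canon)
        if coeffs is not None:
            xyz = refine_site(xyz, coeffs, ops=ops)
            sc = float(harker_score(xyz, pmap)[0])
        canon_r = canonical_site(xyz)
        key = tuple(np.round(canon_r, 4))
        if key not in refined or sc > refined[key].score:
            refined[key] = SiteSolution(xyz=canon_r, score=float(sc))
    ordered = sorted(
        refined.values(), key=lambda s: (-round(s.score, 9), s.xyz)
    )
    return ordered[:max_candidates]


def harker_score(sites: np.ndarray, pmap: Map3D) -> np.ndarray:
    """Mean interpolated σ-height of the three predicted Harker vectors."""
    sites = np.atleast_2d(sites)
    x, y, z = sites[:, 0], sites[:, 1], sites[:, 2]
    half = np.full(len(sites), 0.5)
    hv_w = np.column_stack([2 * x - 0.5, 2 * y, half])
    hv_v = np.column_stack([2 * x, half, 2 * z - 0.5])
    hv_u = np.column_stack([half, 2 * y - 0.5, 2 * z])
    return (
        pmap.interpolate(hv_w) + pmap.interpolate(hv_v) + pmap.interpolate(hv_u)
    ) / 3.0


def anomalous_site_cc(
    sites: np.ndarray, coeffs: pd.DataFrame, ops=None
) -> np.ndarray:
    """Correlation of |ΔF_obs| with the single-site |S(h)| per candidate.

    S(h) = Σ_ops exp(2πi h·(Rx + t)) is the geometric substructure factor;
    for one anomalous site |ΔF| ∝ |S|, so the Pearson correlation across
    reflections scores a site directly against the data, free of any map
    grid quantization (the figure SHELXD-style searches optimize).
    """
    from .crystal import P212121

    ops = ops or P212121
    sites = np.atleast_2d(np.asarray(sites, dtype=float))
    hkl = coeffs[["h", "k", "l"]].to_numpy().astype(float)
    dfo = np.abs(coeffs["dF"].to_numpy())
    out = np.empty(len(sites))
    for i, x in enumerate(sites):
        s = np.zeros(len(hkl), dtype=complex)
        for R, t in zip(ops.R, ops.t):
            s += np.exp(2j * np.pi * (hkl @ (R @ x + t)))
        out[i] = np.corrcoef(dfo, np.abs(s))[0, 1]
    return out


def refine_site(
    site: np.ndarray,
    coeffs: pd.DataFrame,
    *,
    ops=None,
    max_shift: float = 0.03,
) -> np.ndarray:
    """Polish a candidate site by maximizing corr(|ΔF_obs|, |S(h)|).

    The peak-inversion enumeration snaps a coordinate to an exact special
    value (0 or ¼) whenever the corresponding Harker peak sits on a section
    symmetry axis, where the two normalizer-image peaks merge; refining
    against the anomalous differences themselves is smooth in the site and
    moves the estimate off the degenerate point.  Refinements drifting more
    than ``max_shift`` (fractional) are rejected.
    """
    from scipy.optimize import minimize

    x0 = np.asarray(site, dtype=float)

    def neg(v: np.ndarray) -> float:
        return -float(anomalous_site_cc(v, coeffs, ops)[0])

    res = minimize(
        x0=x0,
        fun=neg,
        method="Nelder-Mead",
        options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 250},
    )
    if np.max(np.abs(res.x - x0)) > max_shift or res.fun > neg(x0):
        return x0
    return res.x % 1.0
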