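"""Merging and data-quality statistics with anomalous pairs kept separate.

Observations are mapped to a canonical asymmetric-unit index under the
point group 222 together with a Friedel sign, and the two Bijvoet sides are
merged independently (inverse-variance weighted means).  On top of the
merged table the module computes the standard quality metrics:

* R_merge  = Σ_hkl Σ_i |I_i − ⟨I⟩| / Σ_hkl Σ_i I_i,
* R_p.i.m. = Σ_hkl √(1/(N−1)) Σ_i |I_i − ⟨I⟩| / Σ_hkl Σ_i I_i,
* R_anom   = Σ |I⁺ − I⁻| / Σ (I⁺ + I⁻)/2 over complete Bijvoet pairs,
* CC(1/2)  = half-set intensity correlation over a seeded random split,
* ⟨|ΔF|/σ(ΔF)⟩ per shell, the anomalous signal-to-noise ratio,

and assembles a per-resolution-shell report in the layout of a standard
data-collection table.  R_anom/R_p.i.m. > 1 is the working diagnostic for a
measurable anomalous signal (with the usual caveat that R_anom ignores
redundancy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crystal import P212121, SymmetryOps, UnitCell, reflection_list

__all__ = [
    "MergedReflection",
    "ShellReport",
    "canonical_index",
    "group_observations",
    "intensity_groups",
    "merge",
    "r_merge",
    "r_pim",
    "r_anom",
    "anomalous_flag",
    "cc_half",
    "shell_edges",
    "assign_shells",
    "anom_snr_by_shell",
    "quality_report",
]


@dataclass(frozen=True)
class MergedReflection:
    """A merged Friedel pair; one side may be unobserved (count 0)."""

    hkl: tuple
    I_plus: float
    sigma_plus: float
    n_plus: int
    I_minus: float
    sigma_minus: float
    n_minus: int

    def __post_init__(self) -> None:
        if self.n_plus < 0 or self.n_minus < 0 or self.n_plus + self.n_minus == 0:
            raise ValueError("at least one Bijvoet side must be observed")
        if self.n_plus > 0 and self.sigma_plus <= 0:
            raise ValueError("sigma_plus must be > 0 when observed")
        if self.n_minus > 0 and self.sigma_minus <= 0:
            raise ValueError("sigma_minus must be > 0 when observed")


@dataclass(frozen=True)
class ShellReport:
    """Quality statistics for one resolution shell (or overall)."""

    d_max: float
    d_min: float
    n_obs: int
    n_unique: int
    completeness: float
    multiplicity: float
    mean_i_over_sigma: float
    r_merge: float
    r_pim: float
    r_anom: float
    cc_half: float
    anom_snr: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness <= 1.0 + 1e-9:
            raise ValueError("completeness must be in [0, 1]")
        if np.isfinite(self.cc_half) and not -1.0 - 1e-9 <= self.cc_half <= 1.0 + 1e-9:
            raise ValueError("cc_half must be in [-1, 1]")


# --------------------------------------------------------------------------
# canonical indexing under point group 222 + Friedel sign

# even-sign-flip patterns: reciprocal-space images under 222
_SIGN_PATTERNS = np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=int
)


def canonical_index(hkl: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map signed Miller indices to (asu hkl, Friedel sign, centric flag).

    The asymmetric-unit representative is the all-non-negative image under
    the 222 point group; reflections whose +h and −h orbits share it (any
    zone index zero) are centric and merge with sign +1.
    """
    hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
    images_p = hkl[:, None, :] * _SIGN_PATTERNS[None, :, :]  # (n, 4, 3)
    images_m = -images_p
    nonneg_p = np.all(images_p >= 0, axis=2)  # (n, 4)
    nonneg_m = np.all(images_m >= 0, axis=2)

    has_p = nonneg_p.any(axis=1)
    has_m = nonneg_m.any(axis=1)
    centric = has_p & has_m

    rep = np.empty_like(hkl)
    sign = np.where(has_p, 1, -1)
    # pick the lexicographically largest non-negative image for determinism
    big = int(2 * np.abs(hkl).max() + 2)
    for images, mask in ((images_p, has_p), (images_m, ~has_p)):
        if not mask.any():
            continue
        sub = images[mask]  # (m, 4, 3)
        ok = np.all(sub >= 0, axis=2)
        key = sub[:, :, 0] * big * big + sub[:, :, 1] * big + sub[:, :, 2]
        key = np.where(ok, key, -1)
        best = np.argmax(key, axis=1)
        rep[mask] = sub[np.arange(len(sub)), best]
    sign[centric] = 1
    return rep, sign, centric


def group_observations(obs: pd.DataFrame) -> pd.DataFrame:
    """Attach canonical (h, k, l), Friedel ``sign`` and ``centric`` columns."""
    rep, sign, centric = canonical_index(obs[["h", "k", "l"]].to_numpy())
    out = obs.copy()
    out[["h", "k", "l"]] = rep
    out["sign"] = sign
    out["centric"] = centric
    return out


def intensity_groups(obs: pd.DataFrame) -> list[np.ndarray]:
    """Observation intensities grouped by unique (asu hkl, Friedel sign)."""
    g = group_observations(obs)
    return [
        grp["I"].to_numpy()
        for _, grp in g.groupby(["h", "k", "l", "sign"], sort=True)
    ]


# --------------------------------------------------------------------------
# merging


def merge(obs: pd.DataFrame, ops: SymmetryOps = P212121) -> pd.DataFrame:
    """Merge observations into Bijvoet-separate unique reflections.

    Inverse-variance weighted mean per (asu hkl, Friedel sign); merged
    σ = (Σ wᵢ)^(−1/2).  Observations of (h,k,l) and (−h,−k,−l) are never
    merged together except for centric reflections, where the two sides are
    symmetry-identical.  Returns one row per unique hkl with I_plus/I_minus
    columns (NaN where a side is unobserved).
    """
    if len(obs) == 0:
        raise ValueError("need at least one observation")
    if (obs["sigma"] <= 0).all():
        raise ValueError("all observations have non-positive sigma")
    g = group_observations(obs)
    g = g[g["sigma"] > 0].copy()
    g["w"] = 1.0 / g["sigma"] ** 2
    g["wI"] = g["w"] * g["I"]
    agg = (
        g.groupby(["h", "k", "l", "sign"], sort=True)
        .agg(
            wsum=("w", "sum"),
            wIsum=("wI", "sum"),
            n=("I", "size"),
            centric=("centric", "first"),
        )
        .reset_index()
    )
    agg["I"] = agg["wIsum"] / agg["wsum"]
    agg["sigma"] = 1.0 / np.sqrt(agg["wsum"])

    plus = agg[agg["sign"] == 1].set_index(["h", "k", "l"])
    minus = agg[agg["sign"] == -1].set_index(["h", "k", "l"])
    merged = pd.DataFrame(
        {
            "I_plus": plus["I"],
            "sigma_plus": plus["sigma"],
            "n_plus": plus["n"],
            "centric": plus["centric"],
        }
    ).join(
        pd.DataFrame(
            {
                "I_minus": minus["I"],
                "sigma_minus": minus["sigma"],
                "n_minus": minus["n"],
            }
        ),
        how="outer",
    )
    merged["n_plus"] = merged["n_plus"].fillna(0).astype(int)
    merged["n_minus"] = merged["n_minus"].fillna(0).astype(int)
    merged["centric"] = merged["centric"].fillna(False).astype(bool)
    return merged.reset_index()


# --------------------------------------------------------------------------
# R statistics


def _check_groups(groups: list[np.ndarray]) -> list[np.ndarray]:
    multi = [np.asarray(grp, dtype=float) for grp in groups if len(grp) >= 2]
    if not multi:
        raise ValueError("need at least one group with >= 2 observations")
    return multi


def r_merge(groups: list[np.ndarray]) -> float:
    """Σ|I − ⟨I⟩| / ΣI over multiply-observed groups."""
    multi = _check_groups(groups)
    num = sum(np.abs(grp - grp.mean()).sum() for grp in multi)
    den = sum(grp.sum() for grp in multi)
    if den <= 0:
        raise ValueError("non-positive intensity sum")
    return float(num / den)


def r_pim(groups: list[np.ndarray]) -> float:
    """Multiplicity-weighted (precision-indicating) merging R."""
    multi = _check_groups(groups)
    num = sum(
        np.sqrt(1.0 / (len(grp) - 1)) * np.abs(grp - grp.mean()).sum()
        for grp in multi
    )
    den = sum(grp.sum() for grp in multi)
    if den <= 0:
        raise ValueError("non-positive intensity sum")
    return float(num / den)


def _complete_pairs(merged: pd.DataFrame) -> pd.DataFrame:
    return merged[(merged["n_plus"] > 0) & (merged["n_minus"] > 0) & ~merged["centric"]]


def r_anom(merged: pd.DataFrame) -> float:
    """Σ|I⁺ − I⁻| / Σ(I⁺ + I⁻)/2 over complete acentric Bijvoet pairs."""
    pairs = _complete_pairs(merged)
    if len(pairs) == 0:
        raise ValueError("no complete Bijvoet pairs")
    num = np.abs(pairs["I_plus"] - pairs["I_minus"]).sum()
    den = ((pairs["I_plus"] + pairs["I_minus"]) / 2.0).sum()
    if den <= 0:
        raise ValueError("non-positive intensity sum")
    return float(num / den)


def anomalous_flag(merged: pd.DataFrame, groups: list[np.ndarray]) -> bool:
    """Diagnostic: anomalous signal present when R_anom/R_p.i.m. > 1."""
    return r_anom(merged) / r_pim(groups) > 1.0


# --------------------------------------------------------------------------
# CC(1/2)


def cc_half(groups: list[np.ndarray], seed: int = 0) -> float:
    """Half-set correlation: each group split randomly (seeded) in two,
    Pearson correlation of the half-set means across groups."""
    rng = np.random.default_rng(seed)
    a, b = [], []
    for grp in groups:
        grp = np.asarray(grp, dtype=float)
        if len(grp) < 2:
            continue
        perm = rng.permutation(len(grp))
        half = len(grp) // 2
        a.append(grp[perm[:half]].mean())
        b.append(grp[perm[half:]].mean())
    if len(a) < 3:
        raise ValueError("need >= 3 groups with >= 2 observations")
    return float(np.corrcoef(a, b)[0, 1])


# --------------------------------------------------------------------------
# shells


def shell_edges(d_max: float, d_min: float, n_shells: int = 10) -> np.ndarray:
    """Equal-reciprocal-volume shell boundaries (Å), d_max → d_min."""
    if not d_max > d_min > 0:
        raise ValueError("require d_max > d_min > 0")
    s3 = np.linspace(d_max**-3, d_min**-3, n_shells + 1)
    return s3 ** (-1.0 / 3.0)


def assign_shells(d: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Shell index per reflection; the outermost edge is inclusive."""
    idx = np.searchsorted(-edges, -np.asarray(d), side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)


def anom_snr_by_shell(
    merged: pd.DataFrame, cell: UnitCell, edges: np.ndarray
) -> pd.DataFrame:
    """Per-shell mean |ΔF|/σ(ΔF) from Bijvoet-complete acentric pairs.

    Amplitudes via F = √I with the delta-method σ(F) = σ(I)/(2√I);
    non-positive intensities are skipped and counted.  Infinite ratios
    (σ → 0, e.g. noiseless simulations) are capped and flagged.
    """
    pairs = _complete_pairs(merged).copy()
    if len(pairs) == 0:
        raise ValueError("no complete Bijvoet pairs")
    usable = (pairs["I_plus"] > 0) & (pairs["I_minus"] > 0)
    n_skipped = int((~usable).sum())
    pairs = pairs[usable]
    fp = np.sqrt(pairs["I_plus"])
    fm = np.sqrt(pairs["I_minus"])
    sp = pairs["sigma_plus"] / (2 * fp)
    sm = pairs["sigma_minus"] / (2 * fm)
    dfo = np.abs(fp - fm)
    sdf = np.sqrt(sp**2 + sm**2)
    capped = sdf <= 1e-9 * dfo.mean()
    snr = np.where(capped, np.inf, dfo / np.where(sdf > 0, sdf, np.inf))

    d = cell.d_spacing(pairs[["h", "k", "l"]].to_numpy())
    shell = assign_shells(d, edges)
    rows = []
    for i in range(len(edges) - 1):
        sel = shell == i
        vals = snr[sel]
        finite = vals[np.isfinite(vals)]
        rows.append(
            {
                "d_max": edges[i],
                "d_min": edges[i + 1],
                "n_pairs": int(sel.sum()),
                "anom_snr": float(finite.mean()) if len(finite) else np.nan,
                "n_capped": int(np.sum(~np.isfinite(vals))),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_skipped_nonpositive"] = n_skipped
    return out


# --------------------------------------------------------------------------
# full report


def quality_report(
    obs: pd.DataFrame,
    merged: pd.DataFrame,
    cell: UnitCell,
    d_min: float,
    *,
    ops: SymmetryOps = P212121,
    n_shells: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Shell-by-shell data-collection statistics plus an overall row.

    Completeness is observed unique / theoretically possible unique
    reflections; shells are equal reciprocal volume.  The last row
    (``shell == 'overall'``) aggregates all data.
    """
    theo = reflection_list(cell, d_min, ops)
    d_max = float(theo["d"].max())
    edges = shell_edges(d_max + 1e-6, d_min, n_shells)

    g = group_observations(obs)
    g["d"] = cell.d_spacing(g[["h", "k", "l"]].to_numpy())
    g["shell"] = assign_shells(g["d"].to_numpy(), edges)

    m = merged.copy()
    m["d"] = cell.d_spacing(m[["h", "k", "l"]].to_numpy())
    m["shell"] = assign_shells(m["d"].to_numpy(), edges)
    theo_shell = assign_shells(theo["d"].to_numpy(), edges)

    # Friedel-combined I/sigma on the merged table
    w_p = np.where(m["n_plus"] > 0, 1.0 / m["sigma_plus"] ** 2, 0.0)
    w_m = np.where(m["n_minus"] > 0, 1.0 / m["sigma_minus"] ** 2, 0.0)
    i_all = (
        np.nan_to_num(m["I_plus"]) * w_p + np.nan_to_num(m["I_minus"]) * w_m
    ) / (w_p + w_m)
    m["i_over_sigma"] = i_all * np.sqrt(w_p + w_m)

    snr = anom_snr_by_shell(merged, cell, edges)

    def shell_stats(sel_obs, sel_m, n_theo, d_hi, d_lo, cc_seed):
        sub_obs = g[sel_obs]
        sub_m = m[sel_m]
        groups = [
            grp["I"].to_numpy()
            for _, grp in sub_obs.groupby(["h", "k", "l", "sign"], sort=True)
        ]
        try:
            rm, rp = r_merge(groups), r_pim(groups)
        except ValueError:
            rm = rp = np.nan
        try:
            ra = r_anom(sub_m)
        except ValueError:
            ra = np.nan
        try:
            cc = cc_half(groups, seed=cc_seed)
        except ValueError:
            cc = np.nan
        n_unique = len(sub_m)
        return {
            "d_max": d_hi,
            "d_min": d_lo,
            "n_obs": int(len(sub_obs)),
            "n_unique": n_unique,
            "completeness": n_unique / n_theo if n_theo else np.nan,
            "multiplicity": len(sub_obs) / n_unique if n_unique else np.nan,
            "mean_i_over_sigma": float(sub_m["i_over_sigma"].mean()),
            "r_merge": rm,
            "r_pim": rp,
            "r_anom": ra,
            "cc_half": cc,
        }

    rows = []
    for i in range(n_shells):
        row = shell_stats(
            g["shell"] == i,
            m["shell"] == i,
            int((theo_shell == i).sum()),
            edges[i],
            edges[i + 1],
            cc_seed=seed + i,
        )
        row["shell"] = i
        row["anom_snr"] = snr["anom_snr"].iloc[i]
        rows.append(row)
    overall = shell_stats(
        np.ones(len(g), dtype=bool),
        np.ones(len(m), dtype=bool),
        len(theo),
        edges[0],
        edges[-1],
        cc_seed=seed,
    )
    overall["shell"] = "overall"
    finite = snr["anom_snr"].dropna()
    overall["anom_snr"] = float(
        np.average(finite, weights=snr["n_pairs"][finite.index])
    ) if len(finite) else np.nan
    rows.append(overall)
    return pd.DataFrame(rows)
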