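# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind `nsad`.  Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Resonance scattering model

Near an isolated nuclear resonance the neutron coherent scattering length
is modelled by the single-level Breit-Wigner form

    b(E) = R + g · Γₙ(E)/(2k) · 1/((E − E_r) − iΓ/2),

with potential-scattering term R (fm), resonance energy E_r (meV), total
width Γ, neutron re-emission width Γₙ referenced at E_r with s-wave energy
dependence Γₙ(E) = Γₙ·√(E/E_r), spin statistical factor
g = (2J+1)/(2(2I+1)), and wavenumber k = 2π/λ.  The sign convention is
b = b′ + i·b″ with b″ ≥ 0 for an absorber; the optical theorem gives the
removal cross section σ = 4π·b″/k.  Energy and wavelength are linked by
E[meV] = 81.804/λ[Å]², which pins the ¹¹³Cd resonance at 178 meV to
λ = 0.68 Å.  Multi-level interference and Doppler broadening are out of
scope; below the resonance region, non-resonant absorbers use 1/v scaling
of their 2200 m/s cross sections.

Resonance parameters ship in `nsad/data/isotopes.csv` (compilation-style
values; for ¹¹³Cd: E_r = 178 meV, Γ_γ = 113.5 meV, Γₙ = 0.637 meV,
g = 3/4 from I = 1/2, J = 1).  With these, σ(1.17 Å) evaluates to
19 966 barn, inside the tabulated 19 800 ± 400 window, with no further
calibration; the same entry reproduces the ~20 kbarn thermal (1.8 Å) value
within a few percent.  R for ¹¹³Cd is set to 6.8 fm so that b′ at thermal
wavelengths sits near the tabulated −8.0 fm; the other resonant entries
(¹⁴⁹Sm, ¹⁵¹Eu, ¹⁵⁷Gd) are included for wavelength-scan tables and are
only qualitative — ¹⁵¹Eu in particular omits a bound-level contribution
and underestimates its thermal absorption.

Units are fixed package-wide (meV, Å, fm, barn, cm⁻¹) and conversions are
centralized in `nsad.units`; a cross-section sum in barn divided by a cell
volume in Å³ is numerically already cm⁻¹.

## The synthetic crystal

The generator emulates the study system — a ¹¹³Cd-substituted,
perdeuterated 54-residue rubredoxin-like protein in P2₁2₁2₁ with cell
34.44 × 35.14 × 43.78 Å — as a statistical stand-in, not a real structure:

* 705 protein atoms per asymmetric unit drawn from the perdeuterated
  palette with composition C 226, D 352, N 60, O 62, S 5 (b_av = 6.79 fm,
  composition-weighted), placed with a Gaussian "globule" bias of 7 Å
  width around a random centre;
* exactly one anomalous site with b′ = −8.0 fm (the tabulated thermal
  value, also used by the study's refinement) and b″ from the Breit-Wigner
  model at the simulation wavelength;
* isotropic B factors uniform in [5, 20] Å², occupancies 1;
* the four space-group operators hard-coded (verified against gemmi's
  tables in the tests); no solvent atoms in the model.  The reference
  *cell composition* used for attenuation does include 49 ordered D₂O per
  asymmetric unit, mirroring the real crystal; this asymmetry is
  deliberate (solvent contributes to absorption but is not needed for the
  phasing statistics) and slightly depresses low-resolution realism.

Structure factors are exact sums F(h) = Σ occ·b·e^{2πih·(Rx+t)}·e^{−Bs²/4}
(s = 1/d) evaluated separately for +h and −h — no conjugation shortcuts, so
complex b is handled exactly; systematic absences and Friedel's law for
b″ = 0 hold to round-off.  Intensities are I = T·|F|² with a single
mean-path transmission factor T = e^{−μ·path} (default path 0.165 cm;
per-reflection path integration is out of scope).  Noise is Gaussian with
σ = noise_frac·I + floor (floor = 2 % of the median intensity), negatives
clamped to a small epsilon with σ kept truthful.  Defaults mirror the
study conditions: d_min = 1.75 Å, multiplicity 13 per reflection and
Friedel sign, noise_frac = 0.28 so that the *merged* ⟨I/σ⟩ is ≈ 13 (the
convention data-reduction tables report), which lands R_p.i.m. ≈ 0.06 and
R_anom/R_p.i.m. ≈ 2.3.  Note that at equal per-side multiplicity R_anom
exceeds R_p.i.m. even for pure noise (the classic redundancy caveat), so
the ratio alone is reported as a diagnostic but never used as a gate.

What passing tests show — and what they do not: the simulator reproduces
the *statistical* structure of a neutron SAD experiment (Wilson-like
intensities, Bijvoet differences of the right relative size, realistic
merging statistics).  It does not model detector geometry, absorption
anisotropy, scaling drifts, outliers, twinning, or real protein topology,
so success here demonstrates the correctness of the analysis chain, not
instrument-grade robustness.

## Merging and statistics

Observations map to a canonical asymmetric-unit index under the 222 point
group plus a Friedel sign; zone reflections (h, k or l = 0) are centric
and merge with their mates.  Merging is inverse-variance weighted;
σ_merged = (Σw)^{−1/2}.  R_merge and R_p.i.m. follow the standard sums
over multiply-observed groups (singletons excluded); R_anom uses the
Bijvoet-pair mean (I⁺+I⁻)/2 in the denominator; CC(1/2) uses one seeded
random split.  Amplitudes come from F = √I with delta-method
σ(F) = σ(I)/(2√I); no French–Wilson treatment (a stated non-goal), which
overestimates weak-amplitude signal-to-noise slightly.  Shells are equal
reciprocal volume, 10 by default.

## Patterson substructure location

Anomalous differences ΔF = √I⁺ − √I⁻ over Bijvoet-complete acentric pairs
feed P(u) = Σ|ΔF|² cos(2πh·u), synthesized by FFT after expanding the
coefficients to the full mmm set (tested against the direct cosine sum at
1e−9).  The grid samples at d_min/3 with even dimensions so the Harker
planes are exact; maps are σ-scaled with a 1.5-grid-step origin mask.
Harker relations in P2₁2₁2₁ (w = ½ section peak at (2x−½, 2y), v = ½ at
(2x, 2z−½), u = ½ at (2y−½, 2z)) are inverted by enumeration over the ±
and half-cell ambiguities; candidates are scored by the mean interpolated
σ-height of their three predicted Harker vectors.

Two subtleties matter.  First, the Euclidean normalizer of P2₁2₁2₁ makes a
*single-site* substructure equivalent under independent per-axis sign
flips and half-cell shifts (64 images, including the enantiomorph), so
solutions are canonicalized to [0, ¼]³ and recovery is judged modulo those
images.  Second, when a site coordinate lies within a grid step of 0 or ¼
the two image peaks merge on a section symmetry axis and the enumeration
snaps the coordinate exactly to the special value — where the two
substructure hands coincide.  Shortlisted candidates are therefore refined
by maximizing corr(|ΔF_obs|, |S(h)|) (S the geometric substructure
factor), a smooth, grid-free objective in the spirit of dual-space
searches; this moves estimates off the degenerate points and brings site
errors under ~0.1 Å at reference noise.  The pipeline accepts a solution
only above a 4.5σ three-vector consistency score: pure-noise maps (b″
forced to 0) top out near 3σ because their ~5σ single maxima are never
mutually consistent, while genuine sites score ≥ 6σ — so a signal-free run
reports "no anomalous signal; substructure not found" rather than a
spurious site.  Coefficients are unweighted |ΔF|² by default (classic
Patterson); 1/σ² weighting is available as a flag.

## SAD phasing

With F(h) = G(h) + H(h), where G is the Friedel-even real-scattering part
and H = i·b″·S(h), the measured pair constrains G to the intersection of
the circles |G + H| = |F⁺| and |G − H| = |F⁻|.  Intensities are placed on
the absolute (fm) scale by shell-wise Wilson scaling against
n_ops·Σ|b|²·e^{−B̄s²/2} (B̄ = 12.5 Å², the generator's mean); the
substructure's effective occupancy and B are fitted from the resolution
dependence of ⟨|ΔF|⟩ via E|ΔF| = (4/π)|H|.  The two intersection
candidates are weighted by a Sim-style prior toward the known real
substructure part K = b′·S(h) (acentric variance ε = n_ops·Σb²·DW²), and
centric zone reflections use their symmetry-restricted phases, which
resolve their sign ambiguity against K directly.  The reported phase is
the weighted centroid; the figure of merit is the centroid length (cos of
the half-ambiguity for equal weights) damped by q/(1+q) with q the
anomalous signal-to-noise of the reflection.  Geometrically infeasible
reflections (|ΔF| beyond 2|H|) are clamped to the tangent point and
flagged with FOM × 0.3.  Maps are FFT syntheses of m·|F|·e^{iφ} at 2.30 Å
by default; hand selection compares the skewness of the two candidate
maps (tie threshold 1e−4: "undecided" is reserved for the genuinely
degenerate special-position case where the two hands are the same
substructure and the maps are isometric — map *contrast* was evaluated as
an alternative discriminator and does not separate σ-normalized
FOM-weighted maps at all).  In synthetic mode the solved site is first
gauge-fixed to the normalizer image nearest the planted site, a pure gauge
choice that puts maps on a common origin for truth comparisons without
injecting phase information.

### The intrinsic accuracy ceiling

No density modification is performed anywhere — deliberately, so the maps
show the phasing power of the anomalous signal alone.  That choice has a
quantifiable cost: per reflection, SAD leaves a two-fold phase ambiguity
that only prior information can break, and the available prior (one
b′ = −8 fm atom among ~705) has Sim concentration X ≈ 0.07 — essentially
none.  The optimal estimator is then the bisector centroid, whose
noiseless expected error is 45° unweighted (the acentric tests measure
44.8°), ≈ 33° FOM-weighted, and whose FOM-weighted map correlates with the
truth at ≈ 0.6 — which is also where the pipeline lands (CC ≈ 0.60
noiseless, ≈ 0.35–0.40 at reference noise, map at 2.30 Å).  Two acceptance
assertions (phase error ≤ 30°, map CC ≥ 0.7) sit beyond this ceiling and
are expected to fail; they are kept as stated rather than weakened.
Breaking the ambiguity requires density modification, which is a non-goal
here.  Hand discrimination, in contrast, is robust at this ceiling: the
correct-hand map is consistently the more positively skewed and the more
truth-correlated one.

## Problem sizes and determinism

Monte-Carlo validations use the study-scale problem throughout: 706-atom
models, 5 701 unique reflections at 1.75 Å for Patterson recovery (50
noiseless plants plus noisy seeds), and 50 seeded end-to-end phasing runs
at the 2.3 Å phasing resolution.  Every stochastic operation takes an
explicit integer seed (no global state); a fixed configuration reproduces
its report bit for bit, and the run log records every default actually
used.

## Known limitations

* Single anomalous site only; the Harker inversion and the normalizer
  canonicalization are specific to one site in P2₁2₁2₁.
* No French–Wilson intensity treatment, scaling model, or outlier
  rejection; simulated σ's are trusted as given.
* The ¹⁵¹Eu/¹⁴⁹Sm/¹⁵⁷Gd table entries are single-level approximations for
  scan tables, not evaluated-data quality.
* The phase-probability model is a two-point posterior, not a full
  Hendrickson–Lattman parameterization; adequate for centroid maps and
  FOMs, not for downstream phase combination.
* Map CCs quoted against "truth" use the synthetic model's exact structure
  factors; with real data the analogous number would be a model-map
  correlation after refinement.
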