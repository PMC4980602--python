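"""The whole experiment in one call: simulate → merge → locate → phase.

Runs the reference pipeline preset (rubredoxin cell, λ = 1.17 Å, 13-fold
multiplicity, 2.3 Å substructure cutoff, 2.30 Å map, zero density
modification), then prints the feasibility block, the data-quality summary,
the located site and the hand decision with map correlations against the
known synthetic truth.
"""

from nsad.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=7, d_min=2.3)  # 2.3 A keeps this example quick
report = run_pipeline(cfg)

f = report.feasibility
print("feasibility")
print(f"  sigma_abs(113Cd) = {f['sigma_abs_barn']:.0f} barn, "
      f"mu = {f['mu_cm_inv']:.3f} cm^-1, dF/F = {100*f['delta_f_over_f']:.2f} %")

o = report.overall
print("data quality")
print(f"  {o['n_obs']} obs -> {o['n_unique']} unique, completeness "
      f"{100*o['completeness']:.1f} %, <I/sigma> {o['mean_i_over_sigma']:.1f}")
print(f"  R_merge {o['r_merge']:.3f}, R_pim {o['r_pim']:.3f}, "
      f"R_anom {o['r_anom']:.3f} (ratio {o['r_anom_over_r_pim']:.2f}), "
      f"CC1/2 {o['cc_half']:.3f}")

s = report.substructure
print("substructure")
print(f"  site {tuple(round(float(v), 4) for v in s['sites'][0]['xyz'])}, "
      f"score {s['sites'][0]['score']:.1f} sigma, "
      f"error vs truth {s['site_error_A']:.2f} A")

p = report.phasing
print("phasing (zero density-modification cycles)")
print(f"  selected hand: {p['selected_hand']} "
      f"(skew {p['skew_original']:.3f} vs {p['skew_inverted']:.3f})")
cc = p["map_cc_vs_truth"]
print(f"  map CC vs truth: original {cc['original']:.3f}, "
      f"inverted {cc['inverted']:.3f}")
print("  (the correct hand shows protein-like, positively skewed density;")
print("   the wrong hand decorrelates — the automated analogue of choosing")
print("   the hand by visual inspection)")
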