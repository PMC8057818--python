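"""Recruitment quantification on a simulated smFISH experiment.

Simulates four cocaine conditions (control, acute, repeated, challenge),
derives tertile robust-expressor cutoffs from the control cells, and
summarizes Egr2 recruitment per striatal subdomain. The fractions track
the planted recruitment probabilities: repeated exposure was planted at
half the acute recruitment, and the challenge dose restores most of it.
"""

import striatal_ensembles as se

params = se.SectionSimParams(n_cells=5000, seed=1)
design = [(c, 6) for c in ("control", "acute", "repeated", "challenge")]
cells, truth = se.simulate_experiment(design, params)

thresholds = se.derive_thresholds(cells)
print("tertile cutoffs (puncta/cell):", thresholds.cutoffs)

classified = se.classify_cells(cells, thresholds)
summary = se.recruitment_summary(classified, "Egr2")
means = se.condition_means(summary)
print("\nEgr2 suprathreshold fraction (mean +/- SD over sections):")
for _, row in means.iterrows():
    print(
        f"  {row.condition:>9} {row.region}: "
        f"{row.fraction_mean:.3f} +/- {row.fraction_sd:.3f} "
        f"({row.n_sections} sections)"
    )

# condition effect on section-level fractions, with Tukey post hoc tests
vls = summary[(summary.region == "VLS") & (summary.condition != "control")]
res = se.anova_tukey(vls, "fraction_supra", "condition")
f = res.anova.loc["condition", "F"]
p = res.anova.loc["condition", "p"]
print(f"\none-way ANOVA on VLS fractions: F = {f:.1f}, p = {p:.2g}")
print(res.tukey[["level_a", "level_b", "diff", "p_adj"]].to_string(index=False))
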