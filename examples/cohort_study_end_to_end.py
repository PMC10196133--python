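"""Run a full simulated study: cohort -> outlier screen -> ANOVA -> correlations.

Simulates the default two-genotype (WT vs HOM), three-age (4/6/14 months)
design with 16 animals per cell, screens each group with the ROUT outlier
test, fits genotype x age ANOVAs with Sidak per-age contrasts, and measures
the structure-function associations with Deming regression and Spearman
correlation.
"""

from retinerg import cohortsim

res = cohortsim.run_study(cohortsim.StudyDesign(n_per_cell=16), seed=42)

print("genotype effects (two-way ANOVA p, genotype factor):")
for endpoint in ("ONL", "OPL", "GCIPL", "cone_vmax", "cone_rmp3",
                 "rod_rmp3", "pstr", "TRT"):
    table = res["anova"][endpoint]
    marker = " *" if table.p("genotype") < 0.05 else ""
    print(f"  {endpoint:10s} p = {table.p('genotype'):9.2e}{marker}")

print("\nper-age WT-vs-HOM contrasts for ONL (Sidak-adjusted):")
sidak = res["sidak"]["ONL"].table
for age, row in sidak.iterrows():
    print(f"  {age:4.0f} months: diff = {row['difference']:6.2f} um, "
          f"p_adj = {row['p_adj']:.4f}")

print("\nstructure-function associations (pooled genotypes):")
for pair in (("all_asyn", "ONL"), ("pser129_asyn", "ONL"),
             ("all_asyn", "cone_vmax"), ("ONL", "cone_vmax")):
    corr = res["correlations"][pair]
    sp, dm = corr["spearman"], corr["deming"]
    print(f"  {pair[0]:13s} vs {pair[1]:10s} Rs = {sp.rs:6.3f} "
          f"(p = {sp.p:8.2e}), Deming slope = {dm.slope:8.3f}")

print("\nExpected pattern: outer-retinal (ONL, OPL) thinning and cone-pathway "
      "deficits with a spared pSTR; alpha-synuclein burden correlates "
      "negatively with ONL thickness and cone b-wave amplitude through the "
      "latent severity factor the simulator plants.")
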