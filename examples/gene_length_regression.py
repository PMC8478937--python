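"""Regress per-gene variant counts on gene length within each family.

Generates a synthetic cohort, summarizes it per gene, then fits ordinary
least squares of total / missense / deleterious-missense counts on gene
length (kb) per family with a Bonferroni-adjusted threshold 0.05/18, and
compares per-gene totals across families with a Kruskal-Wallis test.
"""

from pgx_landscape import analyze, classify_all, filter_vqsr
from pgx_landscape.synthetic import SimConfig, generate_panel, generate_variants

config = SimConfig(seed=7)
panel = generate_panel(config)
records, _ = generate_variants(panel, config)
kept, _, _ = filter_vqsr(records, config.vqsr_threshold)
bundle = analyze(classify_all(kept), panel)

kw = bundle.overview["kruskal_wallis_total_counts"]
print(f"Kruskal-Wallis on per-gene totals across families: "
      f"H = {kw['H']:.2f}, p = {kw['p_value']:.3g}")

print(f"\n{'family':<18}{'response':<14}{'slope/kb':>10}{'R^2':>8}{'p':>12}  significant")
for row in bundle.regressions.itertuples(index=False):
    print(f"{row.family:<18}{row.response:<14}{row.slope_per_kb:>10.3f}"
          f"{row.r_squared:>8.3f}{row.p_value:>12.3g}  {row.significant}")

# The generator plants a uniform density of 5 variants/kb, so the 'total'
# slopes recover ~5 in every family; missense and deleterious slopes are
# ~40x and ~70x smaller because only ~2.8% of variants are missense and
# ~58% of those are deleterious.
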