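"""Monte-Carlo behaviour of the reference band across study scenarios.

Each scenario repeatedly draws n=1000 bivariate-normal measurement pairs,
builds the reference band (alpha=0.05, rho_L=0.75) per draw, and records
the percentage of pairs outside the band.  Scenario I sits exactly at the
concordance threshold; II/III are highly concordant at two different
scales; IV has shifted means and unequal SDs.  Run counts are reduced here
so the example finishes in seconds; increase `runs` for tighter medians.
"""

from refband import builtin_scenarios, run_scenario, summarize_runs

registry = builtin_scenarios(runs=500, n_per_run=1000, seed=0)

print(f"{'scenario':<10}{'median CCC':>12}{'median % outliers':>20}"
      f"{'median RB':>12}{'median LoA':>12}")
for name in ("I", "II", "III", "IV"):
    summary = summarize_runs(run_scenario(registry[name]))
    print(
        f"{name:<10}{summary.median_ccc:>12.3f}"
        f"{summary.median_pct_outliers:>20.1f}"
        f"{summary.median_rb_half_width:>12.3f}"
        f"{summary.median_loa_half_width:>12.3f}"
    )

print()
print(
    "At the threshold (I) about 5% of pairs fall outside the band; well\n"
    "above it (II, III) only ~1% do, and doubling the common SD (III)\n"
    "doubles both band widths without changing the outlier rate - the\n"
    "band tracks the scaled CCC, not the raw spread.  With unequal means\n"
    "and SDs (IV) the CCC drops to ~0.6 and ~13% of pairs leave the band."
)
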