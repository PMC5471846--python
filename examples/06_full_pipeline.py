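"""The full analysis: does binding-site position track compartment?

Runs simulate -> annotate -> normalize -> enrich -> target -> associate at
the default study conditions, then contrasts the wildtype run with the
miRNA-depleted scenario on the same seed.
"""

from compartmir import RunConfig, SimConfig, run_full

wt = run_full(RunConfig(sim=SimConfig(rng_seed=1), threshold_stump=True))
dep = run_full(RunConfig(sim=SimConfig(rng_seed=1), scenario="mirna_depleted",
                         threshold_stump=True))

st = wt["stages"]["round"]
sd = st["site_distance"]
assoc = st["association"]
print("wildtype, round spermatids:")
print(f"  mean site distance on RNP mRNAs:      {sd['mean_a']:.0f} nt "
      f"(n={sd['n_a']} sites)")
print(f"  mean site distance on polysome mRNAs: {sd['mean_b']:.0f} nt "
      f"(n={sd['n_b']} sites)")
print(f"  t / Wilcoxon p: {sd['p_t']:.2g} / {sd['p_wilcoxon']:.2g}")
print(f"  compartment association: OR={assoc['odds_ratio']:.1f}, "
      f"chi2={assoc['chi2']:.1f}, p={assoc['p_value']:.2g}")
print(f"  discovered position threshold: "
      f"{wt['position_threshold']['threshold']:.0f} nt")
print(f"  miRNA shift fraction (round->elongating): "
      f"{100 * wt['mirna_shift']['shift_fraction']:.0f}%")

dassoc = dep["stages"]["round"]["association"]
dp = dassoc["p_value"] if dassoc["p_value"] is not None else 1.0
print("\nmiRNA-depleted scenario (same seed):")
print(f"  association p-value: {dp:.2g} (wildtype: {assoc['p_value']:.2g})")
print("  -> depleting the miRNA pool weakens the position-compartment link,")
print("     the in-silico analogue of a miRNA-biogenesis knockout.")
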