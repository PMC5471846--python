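"""Classify RNP/polysome enrichment and find miRNAs shifting compartments.

An entity is RNP-enriched when log2(polysome/RNP) < 0 with Welch t p <=
alpha across replicates (Wilcoxon reported alongside); a shifter is a
miRNA that is RNP-enriched in round spermatids, then drops in RNPs and
rises in polysomes in elongating spermatids.
"""

from compartmir import (
    SimConfig,
    compartment_enrichment,
    detect_shifters,
    simulate_dataset,
    size_factor_norm,
)

ds = simulate_dataset(SimConfig(rng_seed=1))
_, snc = size_factor_norm(ds.counts_sncrna)

records = {
    stage: compartment_enrichment(snc, stage, alpha=0.05)
    for stage in ds.config.stages
}
for stage, rec in records.items():
    n_rnp = (rec["class"] == "RNP").sum()
    n_pol = (rec["class"] == "POLYSOME").sum()
    print(f"{stage:12s} RNP-enriched miRNAs: {n_rnp:2d}  "
          f"polysome-enriched: {n_pol:2d}")

shift = detect_shifters(records, snc, "round", "elongating", alpha=0.05)
print(f"\nRNP->polysome shifters (round -> elongating): "
      f"{len(shift['shifters'])} of {shift['n_rnp_at_from']} "
      f"({100 * shift['shift_fraction']:.0f}%)")
# The generator plants a configurable share of RNP miRNAs that flip to the
# polysome fraction at the last stage; the detector recovers the flips that
# reach significance in both fractions at three replicates.
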