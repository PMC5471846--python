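"""Find canonical seed sites and score them by duplex hybridization energy.

The seed is miRNA nt 2-7; a canonical site is an occurrence of its reverse
complement in the 3' UTR, graded 6mer / 7mer-A1 / 7mer-m8 / 8mer. The
forced-seed minimum free energy clamps the seed helix and optimizes 3'
supplementary pairing within a local window.
"""

from compartmir import MiRNA, find_seed_sites, hybrid_mfe
from compartmir.hybrid import revcomp

let7 = MiRNA("let-7", "UGAGGUAGUAGGUUGUAUAGUU")
print(f"{let7.id}: seed = {let7.seed} (nt 2-7)")

# a UTR with one 8mer site 50 nt after the stop codon
utr = "G" * 49 + revcomp(let7.dna[1:8]) + "A" + "G" * 30
for site in find_seed_sites(let7, utr):
    print(f"site: positions {site.utr_start}-{site.utr_end}, "
          f"type {site.site_type}, {site.distance_to_stop} nt from the stop")

for model in ("simple", "nn"):
    e = hybrid_mfe(let7.sequence, utr, model=model, force_seed=True)
    print(f"forced-seed MFE ({model} model): {e:.2f}")
no_site = hybrid_mfe(let7.sequence, "G" * 40, force_seed=True)
print(f"window without a seed match: {no_site} (the 'no site' sentinel)")
# Energies are comparative: more negative = stronger predicted pairing.
# The nearest-neighbor model uses tabulated RNA stack energies; the simple
# model counts -1 per Watson-Crick pair with a linear loop penalty.
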