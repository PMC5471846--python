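# compartmir

Positional miRNA targeting and the RNP/polysome compartmentalization of
mRNAs during spermiogenesis — as a tested, reusable analysis pipeline with
a planted-truth synthetic-data generator.

## The scientific problem

During spermiogenesis, transcription stops while protein synthesis must
continue: haploid male germ cells store translationally suppressed mRNAs in
ribonucleoprotein particles (RNPs, e.g. the chromatoid body) and translate
them days later on polysomes. Sucrose-gradient fractionation followed by
RNA-seq measures, per transcript and per stage (pachytene spermatocytes,
round spermatids, elongating spermatids), how strongly it partitions
between the RNP and polysome fractions.

The analysis this package implements links that partitioning to **where**
miRNAs bind within 3' UTRs. For entity *i* at one stage, the compartment
call is

    log2 FC_i = log2( mean polysome count_i / mean RNP count_i )

with a Welch *t* test across replicates on log2(count + 0.5),
cross-validated by a Wilcoxon rank-sum test: RNP-enriched when
log2 FC < 0 and p ≤ α, polysome-enriched when log2 FC > 0 and p ≤ α.
Canonical miRNA sites (reverse complement of the seed, miRNA nt 2–7, graded
6mer / 7mer-A1 / 7mer-m8 / 8mer) are located in each 3' UTR and scored by a
forced-seed duplex minimum free energy; each site's *distance to the stop
codon* (position 1 = first nucleotide after the stop) is the key feature.
The hypothesis under test: RNP-enriched mRNAs carry **proximal** sites of
RNP-enriched miRNAs (~365 nt from the stop), polysome-enriched mRNAs carry
**distal** sites (~461 nt), and the miRNA–mRNA compartment pairing is
positively associated (2×2 Pearson χ², odds ratio).

Because the original sequencing data are not reproducible at desk scale,
the package ships a first-class synthetic-data generator that plants the
full structure — two-isoform genes with log10-normal short/long 3' UTRs,
stage- and fraction-resolved negative-binomial count tables with per-sample
depth factors and a 24-gene internal-control panel, proximal/distal 8mer
sites, polyadenylation-site (PAS) records with jitter — so every stage of
the pipeline is validated against known truth.

## Worked example

`examples/06_full_pipeline.py` runs the full analysis (simulate → annotate
CDS/UTRs → PAS-correct 3' ends → normalize → enrichment calls → target map
→ association) and contrasts it with a miRNA-depleted scenario on the same
seed:

```
wildtype, round spermatids:
  mean site distance on RNP mRNAs:      353 nt (n=103 sites)
  mean site distance on polysome mRNAs: 487 nt (n=121 sites)
  t / Wilcoxon p: 2.1e-13 / 2e-29
  compartment association: OR=99.9, chi2=46.3, p=9.9e-12
  discovered position threshold: 414 nt
  miRNA shift fraction (round->elongating): 17%

miRNA-depleted scenario (same seed):
  association p-value: 3.2e-05 (wildtype: 9.9e-12)
  -> depleting the miRNA pool weakens the position-compartment link,
     the in-silico analogue of a miRNA-biogenesis knockout.
```

Reading the numbers: sites on RNP-classed mRNAs sit ~134 nt closer to the
stop codon than sites on polysome-classed mRNAs (planted means 365/461 nt,
shifted slightly by clipping on short UTRs), both tests agree the gap is
real, and mRNAs targeted by RNP-enriched miRNAs are overwhelmingly the
RNP-enriched ones (odds ratio ≫ 1). A depth-1 decision tree recovers a
separating distance threshold of ~414 nt, the midpoint of the planted
means. Ablating 80% of the miRNA pool removes most planted recruitment and
the association weakens by seven orders of magnitude.

The other examples each exercise one capability: dataset generation,
UTR annotation + PAS correction, the three normalization routes,
enrichment/shifter detection, and seed-site discovery with hybridization
energies.

## Command line

A thin CLI mirrors the pipeline stages:

```bash
compartmir simulate --seed 1 --outdir sim/
compartmir annotate-utr --fasta sim/transcripts.fasta --pas sim/pas.bed --out annotated.tsv
compartmir run --seed 1 --outdir run/        # full pipeline + report.json
```

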