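# tfcensus

Prediction and genomic-context analysis of DNA-binding transcription
factors (TFs) in bacterial and archaeal genomes.

TFs — DNA-binding proteins that activate or repress transcription, excluding
sigma factors and RNA-polymerase subunits — make up a genome-size-dependent
share of a prokaryote's proteome. `tfcensus` is for comparative genomicists
who want to (i) call the TF repertoire of annotated genomes by two
complementary evidence routes, (ii) characterise each TF gene's
neighborhood, (iii) layer enzymatic and virulence annotations on top, and
(iv) analyse how TF abundance scales with genome size — all on inputs that
are plain tabular exports of standard tools (pfam_scan-style domain hits,
BLAST-tabular similarity hits, EC tables), so the heavy scanning stays
outside the package.

## The methods in brief

**Dual-route TF calling.** A protein is a TF if it carries a hit to one of
the 111 TF-associated PFAM domain families at E ≤ 10⁻³ (domain route),
and/or forms a reciprocal best hit (RBH) with a curated, experimentally
validated TF catalog at E ≤ 10⁻⁵ with alignment coverage ≥ 70% on both
sides (orthology route). Merged calls carry a provenance label
(`domain_only` / `both` / `orthology_only`) so each route's contribution is
auditable.

**Genomic context.** Transcription units (TUs/operons) are maximal runs of
same-strand adjacent genes with intergenic gaps ≤ 50 bp. Each TF gene is
classified as *divergent* (its promoter-side neighbor is on the opposite
strand, both promoters facing the shared intergenic region — the classic
regulator/target architecture), *in_tu* (co-transcribed with a neighbor) or
*isolated*.

**Functional layers.** Per family, pooled across genomes: divergent
fraction, in-TU share, enzyme association (≥ 1 EC number), and virulence
association (RBH against a virulence-factor reference set, same thresholds
as orthology). Neighbor-gene domain content is tested for enrichment with
one-tailed Fisher exact tests, Benjamini–Hochberg FDR control at α = 0.05,
and pfam2go GO annotation.

**Scaling law.** TF count *y* versus ORF count *x* is fit both as a power
law *y = a·xᵇ* (ordinary least squares on log–log scale) and as a line
*y = a + b·x*; per taxonomic division the model with the higher R² on its
own scale is selected.

A fully ground-truthed synthetic-data generator (`tfcensus.synthetic_data`)
emits complete input bundles — gene layouts with planted divergent pairs
and operons, evidence tables with near-threshold decoys, catalogs, division
panels — so every stage is testable end to end without downloads.

## Worked example

```bash
tfcensus fixtures --out-dir demo --seed 42 --n-genomes 12 --orf-min 300 --orf-max 1500
tfcensus run --input-dir demo --out-dir demo_out --top-k-families 5
```

The run log reports each stage's volume:

```
INFO tfcensus: loaded 12 genomes from demo (12 rows rejected)
INFO tfcensus: predict: 268 TF calls, 12 genomes
INFO tfcensus: context: 10290 TUs, 268 TF context calls
INFO tfcensus: annotate: 5 family rows
INFO tfcensus: enrich: 17 tests
INFO tfcensus: scaling: 4 fit rows
pipeline complete: demo_out (config bfc1bc041705c82e)
```

(the 12 rejected rows are the generator's planted malformed decoys — one
invalid EC row per genome — caught by input validation). `demo_out/`
then contains nine TSV reports plus a manifest. For example,
`family_context.tsv` gives the per-family context/function tallies, with
the divergent share as a fraction and the rest as percentages:

```
family_pfam  total_tfs  n_divergent  frac_divergent  n_in_tu  pct_in_tu  n_enzyme  pct_enzyme  n_virulence  pct_virulence
PF00440      35         5            0.1429          8        22.8571    2         5.7143      2            5.7143
PF00486      29         6            0.2069          7        24.1379    1         3.4483      1            3.4483
```

i.e. of the 35 TetR/AcrR (PF00440) TFs called in this small collection, 5
are divergently paired with a neighbor and 8 sit inside predicted operons.
`scaling.tsv` reports both abundance fits and the selected model:

```
division  model   a        b       r2      pearson_r  n   selected
overall   power   0.00119  1.4438  0.9546  0.9770     12  True
overall   linear  -6.3603  0.0328  0.9419  0.9705     12  False
```

The recovered exponent b ≈ 1.44 estimates, from just 12 genomes, the
super-linear scaling the collection was generated under (b = 1.5283); at
500 genomes the estimate lands within ±0.05 of the generator value.

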