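# Methods

This note documents the models, conventions and design choices behind
`tfcensus`, in the spirit of a statistical-methods appendix: what each
component assumes, which knobs matter, and what the synthetic-data tests do
and do not demonstrate about real genomes.

## Coordinates and distances

All gene coordinates are 1-based inclusive (GFF3 convention) with
`end >= start` regardless of strand. The intergenic distance between two
ordered, non-overlapping genes is the number of bases strictly between
them, `downstream.start - upstream.end - 1`; abutting genes are at distance
0, and overlapping genes are clamped to 0 with an explicit overlap flag
rather than reported as negative (overlapping divergent promoters are a
real and biologically meaningful configuration, so the flag is preserved
through the context tables).

PFAM accession version suffixes (`PF00126.27`) are stripped at parse time
so the TF-family list matches across PFAM releases.

## Dual-route TF calling

* **Domain route.** A protein qualifies iff it has at least one hit to a
  TF-associated PFAM family with E ≤ `domain_e_max` (default 10⁻³).
  Overlapping within-clan hits are all retained by the parsers; the family
  assignment takes the single best qualifying hit, with a fully
  deterministic tie-break (minimum E-value, then maximum bit score, then
  lexically smallest accession) so repeated runs are identical.
* **Orthology route.** Reciprocal best hit against a curated catalog. A
  similarity hit qualifies iff E ≤ `ortho_e_max` (default 10⁻⁵) and
  alignment coverage ≥ `cov_min` (default 0.70). "Coverage ≥ 70%" is
  enforced on **both** alignment sides by default — the stricter and more
  symmetric reading — with a one-sided query-coverage mode available for
  sensitivity analysis. Best-hit selection is max bit score, tie-broken by
  min E-value then lexical subject id. RBH is the auditable core of
  graph-based orthology tools; full graph clustering across many proteomes
  is deliberately out of scope since the use case here is pairwise
  detection against a reference set.
* **Merge.** The provenance partition (`domain_only` / `both` /
  `orthology_only`) is disjoint and covers exactly the union of both call
  sets. Orthology-only calls are emitted with an empty family: inheriting
  the matched catalog entry's family would silently mix evidence levels,
  so family labels always trace to a domain hit. Their `best_e` is left
  unset unless a similarity E-value is supplied.

Note that while the domain route is monotone in its threshold (relaxing
`domain_e_max` only adds calls), RBH is not strictly monotone in general:
a relaxed coverage cutoff can admit a new best hit that breaks a
previously reciprocal pair. In practice, with well-separated synthetic
evidence, relaxation only adds calls.

## Transcription units and context

TUs are maximal runs of consecutive same-strand genes with adjacent gaps
≤ `tu_gap_max`. The default of 50 bp is the conventional intergenic-distance
heuristic for prokaryotic operon calling; it is exposed in the pipeline
config. Every gene belongs to exactly one TU (strand switches and large
gaps both break runs; overlapping same-strand genes count as gap 0 and
stay joined).

Context classification keys on the **upstream (promoter-proximal)
neighbor**: a plus-strand TF whose left neighbor is on the minus strand,
or a minus-strand TF whose right neighbor is on the plus strand, is
*divergent* — the two promoters then face the shared intergenic region,
the LysR-paradigm arrangement in which a TF regulates the adjacent gene
while repressing itself. Divergence carries no distance cutoff; the
distance distribution is reported separately (histogram plus the share of
pairs within 100 bp). A TF sharing a TU with at least one other gene is
*in_tu* (its partner is the nearest co-TU neighbor); everything else is
*isolated*. The three classes are exhaustive and mutually exclusive, and a
divergent partner can never be a co-TU member because TUs are same-strand
by construction.

Replicons are linear by default. With `circular=True` neighborhoods wrap
around the origin; since gene records do not carry the replicon length,
the wrapped intergenic distance is approximated by the leading span before
the first gene. A TF at a linear replicon edge with no upstream neighbor
cannot be divergent and is classified by TU membership alone.

## Functional layers

A protein is enzyme-associated iff it has at least one syntactically valid
EC number (class digit 1–6; trailing `-` fields, i.e. partial ECs, count).
The class distribution is computed over EC entries for classes 1–6
(oxidoreductases … ligases). Virulence association reuses the RBH
machinery unchanged against a virulence-factor reference set — this
equivalence is property-tested, not assumed.

The per-family table pools each family's TFs across all genomes. Its
denominators are the family's total TF count. The divergent column is
printed as a fraction while the other columns are percentages; this mixed
scale is the convention the table is reported in and is preserved rather
than harmonised. Enzyme and virulence flags are computed for TF proteins
and for divergent-neighbor proteins separately (the neighbor panels appear
in the EC-distribution and virulence reports).

## Enrichment statistics

One-tailed Fisher exact tests (upper tail only — enrichment, not
depletion) compare, for each domain family observed among a TF family's
divergent neighbors, its foreground rate against a background. The default
background is the pooled divergent neighbors of all analysed families;
the alternative `all_proteins` background is available because the choice
of background is genuinely open and materially affects p-values. p-values
are adjusted per family with Benjamini–Hochberg step-up FDR control;
significance is `fdr ≤ alpha` (default 0.05). GO terms are attached via a
pfam2go mapping. Implementation uses `scipy.stats.fisher_exact` and
`statsmodels` multipletests; the test suite verifies Fisher p-values
against exhaustive hypergeometric enumeration for every table with margins
≤ 12, and BH against hand-computed step-up cases.

## Scaling analysis

The power fit is ordinary least squares of log *y* on log *x* —
closed-form, deterministic and the convention for scaling-law exponents;
a nonlinear least-squares fit can differ in the third decimal. Zero-TF
genomes cannot enter the log fit and are excluded from it with a warning
(the linear fit keeps them). R² and the Pearson correlation are reported
on each model's own scale. Per-division model selection compares the two
R² values; divisions with fewer than 10 genomes are skipped, and an R² gap
below 0.01 is reported as `ambiguous` rather than forced — noise-free
proportional data (*y = ax*) is fit exactly by both models and is the
canonical ambiguous case.

## The synthetic-data generator

The generator is first-class, tested code. Its defaults are the study
conditions used throughout the tests:

| parameter | default | rationale |
|---|---|---|
| scaling a, b | 0.0007, 1.5283 | the documented abundance power law |
| noise sigma (log scale) | 0.2 | moderate multiplicative scatter around the law |
| ORF range | 500–12 000, log-uniform | spans typical prokaryotic genome sizes |
| family frequencies | TetR/AcrR 0.098, OmpR/PhoB 0.079, … (top 10 ≈ 0.57) | anchored to the curated-collection distribution; the remainder spreads over a 101-family minor tail so the TF-associated list has 111 entries |
| divergent / in-TU fractions | 0.25 / 0.30 | mid-range of the per-family context tallies |
| divergent gap | geometric, mean 60 bp | most divergent pairs fall within 100 bp |
| intra-TU gap | geometric mean 20 bp, truncated at 45 bp | strictly below the 50 bp TU threshold so planted operons are unambiguous |
| inter-element gap | 51 bp + geometric(mean 250) | strictly above the threshold so TUs never bridge planted elements |
| detectability (domain / orthology) | 0.90 / 0.70 | matches the observed provenance-partition shares in model organisms |
| enzyme / virulence fractions | 0.05 / 0.10 | within the per-family reported ranges |
| EC class mix | (0.15, 0.40, 0.20, 0.10, 0.10, 0.05) | transferase-dominant, as observed |

Catalog generation uses role frequencies 29.4% repressor / 23.9% dual /
18.1% activator / 28.6% undefined and domain-count frequencies 41.77% /
50.22% / 6.03% / small ≥ 4-domain tail, with 1–3 evidence codes per entry
drawn uniformly from the 17 recognised codes (per-entry evidence
multiplicity is not constrained by the aggregate curation statistics, so a
modest 1–3 range was fixed once).

Genes are laid on one circular replicon per genome at a fixed 900 bp
length (a typical prokaryotic ORF) — only gaps matter downstream. Layout
guarantees each planted context label: divergent TFs are preceded by an
opposite-strand partner at a short gap; in-TU TFs sit in the interior of a
same-strand run; isolated TFs get a same-strand upstream filler beyond the
TU threshold; plain fillers pad both replicon ends so no TF sits at an
edge. Every bundle contains mandatory near-threshold decoys: a domain hit
at exactly E = 10⁻³ (passes) and one just above (fails), an RBH pair at
exactly E = 10⁻⁵ and coverage 0.70 (passes), pairs failing only coverage or
only reciprocity, and one malformed EC row (exercises rejection paths).
Divergent-neighbor genes receive domain annotations from a small pool of
transport/kinase/metabolic families with a mild family-dependent bias, so
the enrichment stage has real signal to find. All randomness flows from a
single seeded NumPy generator per collection; identical configs produce
byte-identical bundles.

Count-level quantities (TF count versus ORF count) are drawn by a shared
sampler that skips gene layout entirely, so scaling studies run on
hundreds of genomes in milliseconds while full-layout bundles are kept to
tens of genomes with a few hundred to a couple of thousand ORFs each in
the test suite — the same model at sizes chosen for fast, deterministic
tests.

**What passing tests show — and don't.** Perfect recovery of planted
families, provenances and contexts demonstrates the machinery is correct
under evidence that is consistent with its thresholds by construction. It
does not demonstrate robustness to real-data pathologies the generator
deliberately omits: fragmented or mis-annotated gene models, domain
architectures shared between TFs and non-TFs, paralog-rich families where
RBH undercalls, horizontally transferred context, or multi-replicon
genomes. Those require real benchmarks.

## Pipeline mechanics

The CLI stages (`predict`, `context`, `annotate`, `enrich`, `scaling`,
`report`) each check their prerequisite artifacts and can be run
independently; `run` chains the very same stage functions, so staged and
monolithic execution produce identical bytes. Configuration comes from
YAML with flag overrides (flags > file > defaults) and is validated before
any compute; a short SHA-256 hash of the full config is stamped into the
manifest entry of every output file. On failure the monolithic runner
removes partial outputs. All outputs are headered TSVs; parsers never drop
rows silently (reject counts and diagnostics are carried alongside
accepted records).

## Known limitations

* RBH against a single reference set cannot separate orthologs from
  recent paralogs; family labels therefore never come from the orthology
  route.
* TU prediction from strand and distance alone ignores promoter and
  terminator signals; the 50 bp default trades sensitivity for precision.
* The circular-replicon wraparound distance is approximate (see above).
* Enrichment p-values depend strongly on the background definition; both
  supported backgrounds are simple conventions, not ground truth.
* The per-family table's mixed fraction/percent scale is preserved for
  comparability and can surprise downstream consumers.
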