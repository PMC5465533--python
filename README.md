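# lnctissue

Tissue-specificity-aware ranking of lncRNA–mRNA interactions.

## The problem

Most human long non-coding RNAs are expressed in only one or a few
tissues, while protein-coding genes are far more often ubiquitous.  Some
tissue-restricted lncRNAs (the epidermal lncRNA TINCR is the canonical
example) act by base-pairing with mRNAs and upregulating them, which means
a lncRNA and its genuine target mRNAs should share the same tissue
specificity.  Purely sequence-based interaction prediction — ranking every
candidate mRNA by predicted RNA–RNA hybridisation energy — drowns in the
size of the transcriptome.  `lnctissue` implements the natural fix:
restrict the candidate mRNAs to those specifically expressed in the
lncRNA's own tissue(s) before ranking by energy, and quantify how much
that restriction improves retrieval of experimentally validated targets.

The package is aimed at computational RNA biologists who have (a) a
gene × tissue FPKM matrix from a multi-tissue RNA-seq compendium, (b) a
table of predicted local lncRNA–mRNA interaction sites with energies
(e.g. exported from an RNA–RNA interaction database), and (c) a list of
validated target mRNAs for at least one lncRNA of interest.  A seeded
synthetic-data generator reproduces the statistical structure of all three
inputs, so the entire pipeline is testable without downloads.

## The method

**Tissue specificity.**  Expression is filtered to genes with ≥ 1 FPKM in
at least one tissue, then log2(FPKM+1)-transformed.  For each gene profile
*x* over *N* tissues, values are reduced to absolute deviations from the
one-step Tukey biweight location, normalised to a probability vector *p*,
and scored by Shannon entropy, ROKU style:

    H = − Σᵢ pᵢ log₂ pᵢ ,      score = log₂(N) − H .

The score runs from 0 (ubiquitous) to log₂ N (single-tissue).
Separately, outlier tissues are assigned by trimming the sorted profile:
every assignment of L low and R high outliers (L + R ≤ ⌊N/4⌋ by default)
is scored with the penalised objective

    U(L, R) = (N − L − R) · ln(s² + ε) + w·(L + R + 1) ,

where s² is the variance of the retained values; the minimiser yields a
per-tissue assignment in {+1, 0, −1}.  A gene is *specifically expressed*
if any tissue is flagged; a gene belongs to tissue *t*'s gene set if it is
flagged +1 (over-expressed) there.

**Interaction ranking.**  Local interaction sites are aggregated per
lncRNA–mRNA pair into two statistics: `MinEnergy`, the most stable single
site, and `SumEnergy`, the sum of site energies at or below −16 kcal/mol.
Candidate mRNAs are ranked most-negative-first (pairs with no qualifying
site rank last, ties break by MinEnergy then mRNA ID).

**Evaluation.**  For a candidate set of size *M* containing *K* validated
targets, the pipeline traces the cumulative true positives among the top
*n* predictions (n = 1..100 by default) against the random-guess
expectation *nK/M* (the hypergeometric mean), and tests enrichment of
validated targets in each tissue-specific candidate subset against the
remaining initial candidates with a one-tailed Fisher's exact test,
Bonferroni-corrected over tissues.

## Worked example

Generate a synthetic benchmark (16 tissues, 300 lncRNAs, 700 mRNAs, one
focal lncRNA with 40 validated targets), profile specificity, and evaluate
predictions:

```bash
lnctissue simulate --out demo --seed 1
lnctissue specificity --expression demo/expression.tsv \
    --catalog demo/catalog.tsv --out demo/profiles.tsv
# INFO lnctissue: lncRNA: 300 genes profiled, 80.0% specifically expressed
# INFO lnctissue: protein_coding: 700 genes profiled, 52.6% specifically expressed

lnctissue predict --expression demo/expression.tsv --catalog demo/catalog.tsv \
    --sites demo/sites.tsv --truth demo/truth.txt \
    --focal-lncrna LNC0001 --out demo/pred
# INFO lnctissue: focal lncRNA LNC0001 is specifically expressed in: tissue01
```

The specificity summary shows the expected contrast: 80% of lncRNAs but
only ~53% of coding genes are tissue-specific.  The evaluation tables tell
the main story.  Ranking all 700 initial candidates by SumEnergy finds 22
validated targets in the top 100 (`demo/pred/evaluation_initial.tsv`,
random guessing would find 5.7); restricting to the 56 tissue01-specific
candidates finds 32 (`demo/pred/evaluation_tissue_tissue01.tsv`).  The
enrichment table (`demo/pred/enrichment.tsv`) shows why:

```
tissue    a   b   c   d    odds_ratio  p         p_bonferroni
tissue01  32  24  8   636  106.0       1.23e-32  1.97e-31
```

32 of the 56 tissue01-specific candidates are validated targets, versus 8
of the remaining 644 — the focal tissue's candidates are massively
enriched, so the restricted ranking retrieves more targets even though it
ranks far fewer candidates.

The same analysis is available as library functions
(`lnctissue.simulate_expression`, `profile_genes`, `rank_candidates`,
`tp_curve`, `fisher_enrichment`, ...) for use in notebooks and scripts.

## Limitations

The built-in duplex scanner (`scan_duplex`) is a documented toy: maximal
ungapped antisense complementarity with additive per-pair energies and no
accessibility, mismatch or loop terms.  Real analyses should import site
tables from a dedicated RNA–RNA interaction predictor.  See
`docs/methods.md` for the model details, parameter defaults, and what the
synthetic benchmark does and does not emulate.
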