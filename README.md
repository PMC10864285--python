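# ovascreen

Tools for a genome-scale meiosis/fertility gene screen in *Drosophila
melanogaster*: tissue-enrichment candidate selection from replicate
expression data, scoring of RNAi knockdown crosses with the
X-chromosome nondisjunction (NDJ) statistic, gene-level phenotype
aggregation, and hypergeometric gene-set overrepresentation with PPI
subnetwork extraction. A synthetic-data generator with planted ground
truth lets the whole pipeline run and be tested without any downloads.

The package is aimed at fly geneticists running ovary-centred RNAi
screens and at anyone reanalysing or extending published screen tables
of the "STERILE / ND / total, k NDJ" form.

## The statistics at the core

**Enrichment funnel.** For each gene and tissue, enrichment is
E = mean(tissue) / mean(whole body) over biological replicates, with a
two-tailed pooled-variance Student's t-test. A tissue is called *up*
when E > 1 and p ≤ 0.05, *down* when E < 1 and p ≤ 0.05, *others*
otherwise. Probe sets with no detection ("present") call in ovary,
testis, or larval CNS are removed, one representative probe is kept per
gene, and genes are classified as ovary_only, ovary+CNS, ovary+testis,
or ovary+CNS+testis; an *up* call in any other tissue rejects the gene.

**NDJ frequency.** In the test cross, females carrying a
germline-driven shRNA are mated to X / B^S Y males. Normal segregation
gives X/X daughters and X/B^S Y sons; maternal X nondisjunction gives
X/O sons and X/X/B^S Y daughters, while the reciprocal XXX and YO
zygotes die. The scored frequency doubles the exceptional classes to
correct for the dead half:

    NDJ = 2(XO + XXY) / [ 2(XO + XXY) + X/X + X/Y ]

A line is *positive* when, in either germline driver (MVD1 or matα), it
is sterile, its NDJ frequency reaches 1.7% (compared after rounding to
one decimal in percent), or its brood (adjusted total) is ≤ 100. A gene
is positive when any of its shRNA lines is; its Venn region is the
exact set of evidence categories {Sterile, NDJ, Small_brood}.

**Overrepresentation.** Terms sharing at least two genes with the input
set are tested with the hypergeometric upper tail P(X ≥ k) and corrected
by Benjamini–Hochberg; PPI edges with combined score ≥ 0.4 define the
subnetwork whose connected components are reported.

## Worked example

Score the packaged screen-results table (94 genes × 110 shRNA lines):

```sh
$ ovascreen score --out out/score
94 positive genes (29 Sterile-only, 24 NDJ-only, 18 Small_brood-only, 23 in overlaps)
```

The 94 genes split into 29 whose only evidence is sterility, 24 with
only an elevated NDJ rate, 18 with only a small brood, and 23 that fall
in Venn overlap regions (different phenotypes between drivers or
shRNAs). `out/score/` contains per-line and per-gene call tables, the
full 7-region Venn summary, and a manifest recording every threshold.

The same numbers from Python:

```python
>>> from ovascreen import packaged_table1, parse_screen_table, score_screen, ndj_percent
>>> calls = score_screen(parse_screen_table(packaged_table1()))
>>> sum(c.positive for c in calls)
94
>>> ndj_percent(226, 18)   # the strongest NDJ cross in the table
15.9
```

An end-to-end run on synthetic data with planted truth:

```sh
ovascreen run --seed 3 --out out/demo
```

which simulates a 200-gene expression matrix and screen table, selects
candidates through the funnel, and scores the crosses; `truth.json`
carries the planted labels for comparison.

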