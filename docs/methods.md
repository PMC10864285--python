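# Methods

## Scope and pipeline

The package implements the computational side of an ovary-centred
meiosis/fertility RNAi screen in four stages:

1. **Selection** (`ovascreen.microarray`) — tissue-enrichment calls on
   a replicate expression matrix and the four-group classification.
2. **Prioritization** (`ovascreen.prioritize`) — novelty (bare CG
   numbers), RNAi stock availability, ortholog annotation, and
   single-cell germline bias.
3. **Cross scoring** (`ovascreen.ndj`) — the NDJ statistic, line and
   gene positivity, and Venn aggregation.
4. **Set statistics** (`ovascreen.enrich`) — hypergeometric
   overrepresentation with BH correction and PPI subnetworks.

`ovascreen.simulate` generates every input with planted truth;
`ovascreen.cli` and `ovascreen.io` provide the command-line surface,
readers, and run manifests. Wet-lab stages of such screens (husbandry,
qPCR validation, cytology) are out of scope; ortholog inference is
consumed as a table, never computed.

## Models and procedures

### Enrichment calls

Enrichment for gene g in tissue t is E = mean_t / mean_wb over
biological replicates on the linear intensity scale. Significance uses
the classic pooled-variance two-sample Student's t-test
(df = n1 + n2 − 2); Welch's correction is available behind a flag but is
not the default, since equal-variance Student is the conventional
reading of "Student's t test" in microarray screens. Direction is
*up* iff E > 1 (strict) and p ≤ 0.05 (inclusive), *down* iff E < 1 and
p ≤ 0.05, else *others* — a complete partition.

Degenerate inputs: with fewer than two replicates on either side the
test is undefined; the call is forced to *others* with a
`too_few_replicates` flag rather than raising, so one bad probe cannot
stop a funnel run. When both samples have zero variance the t statistic
is taken in the limit: p = 1 for equal means, p = 0 otherwise. A
non-positive whole-body mean raises, because enrichment is undefined.

Symbol filtering removes unknown genes ("---"), non-protein-coding
CR-number genes, RNA genes (symbols containing "rna", which in fly
nomenclature appears as an infix: `snoRNA:...`, `tRNA:...`), and
ribosomal proteins (`rp[sl]` followed by a digit, catching RpS/RpL and
mitochondrial mRpS/mRpL). A multi-gene `///` probe set is removed only
when *every* component matches a removal pattern, since the probe still
reports on a protein-coding gene if any component is one.

The representative probe per gene maximises (number of present
replicate flags across ovary/testis/CNS, number of *up* calls among
those tissues); exact ties break to the lexicographically smallest
probe id, a deterministic convention chosen because no biological
tiebreak is available.

The tissue panel is configuration, not code: the whole-body reference,
the three special tissues, and an exclusion list (cultured-cell
columns) are named in `TissuePanel`.

### NDJ scoring

The estimator NDJ = 2(XO+XXY)/[2(XO+XXY)+XX+XY] doubles the scored
exceptional progeny because the reciprocal exceptional zygotes (XXX,
YO) are inviable: each scored exceptional fly stands for two
exceptional zygotes. Summary cells "total, k NDJ" are read as
(adjusted total = the formula's denominator, k = exceptional progeny),
the reading under which the strongest cross in the packaged table
(226, 18) reproduces its published 15.9%; a config flag allows the
alternative reading.

Positivity conventions, all recorded in the run manifest:

* The NDJ percentage is rounded to one decimal before comparison with
  the 1.7% threshold (default `ndj_rounding_decimals: 1`). Several
  published rows are hits only under rounding — e.g. 2·1/119 = 1.68%
  prints and scores as 1.7% — so rounding is the convention that
  reproduces the published calls; `none` compares raw values.
* Small brood is adjusted total ≤ 100 (inclusive by default,
  configurable to strict <; on the packaged table the two agree since
  no total equals exactly 100).
* A sterile cross is not additionally counted as small-brood: the
  categories represent distinct evidence.
* "ND" and empty cells carry no evidence; a line with only ND entries
  is *untested*, never negative.
* Replicate rows for the same gene × shRNA are pooled into one line
  call; whole-body-driver (Tub-Gal4) and oocyte-morphology columns are
  annotations and never affect positivity.

A gene is positive when any line is; its categories are the union over
positive lines and its Venn region is that exact subset, so the seven
region counts partition the positive genes.

### Overrepresentation and PPI

The test is the upper tail P(X ≥ k) of Hypergeometric(N, K, n) — the
standard overrepresentation direction. Terms overlapping the input in
fewer than two genes are dropped *before* testing, and BH runs across
the retained terms only, mirroring the report-only-multi-gene-terms
convention of pathway servers. The background defaults to the union of
the term collection's members because servers' internal backgrounds are
generally unpublished; it is configurable, and published q-values are
background-dependent, so they are not reproduction targets. Input genes
outside the background are dropped (strict mode raises). PPI edges are
deduplicated keeping the maximum score, self-loops removed, and edges
below the combined-score threshold (default 0.4, inclusive) discarded;
components are reported largest first with a deterministic tiebreak.

Note that BH q-values are *not* idempotent under re-application (the
m/rank multipliers change when q replaces p); the implementation
guarantees monotonicity and order preservation instead.

## Synthetic data: what it emulates and what it does not

`simulate_expression` draws log-normal intensities around a base mean
of 100 units with sd 0.25 on the log scale, four replicates per tissue,
over a seven-tissue panel (whole body; ovary, testis, larval CNS; and
three somatic tissues: head, midgut, fat body). Planted genes receive a
4-fold multiplicative effect in the tissues of their intended group. A
replicate is "present" when it clears a detection floor set at the base
mean — a documented constant, not a fitted one. These are the study
conditions of the test bench; under them the funnel's expected
per-gene sensitivity is about 0.93 (a planted gene is lost when a noise
tissue crosses the up cutoff, ~2.5% per somatic tissue) and the
false-positive rate is a few percent. The generator does not emulate
probe-level cross-hybridisation, correlated replicates, batch effects,
or the long-tailed intensity distributions of real arrays, so passing
recovery tests demonstrates correctness of the funnel logic, not
performance on real microarray data.

`simulate_cross` is an egg-level model: egg count ~ Poisson(brood
mean); each egg is nondisjunction-derived with probability d; diplo-X
and nullo-X ova are equally likely, as are X and B^S Y sperm; XXX and
YO zygotes are removed before tallying. The factor-2 correction in the
estimator is therefore *tested against the mechanism* rather than
assumed — the scored frequency is a consistent estimator of d, and the
expected survivor fraction is 1 − d/2. Meiosis-II errors, autosomal
nondisjunction, viability differences among survivor classes, and
driver-timing effects are not modelled; d is a per-egg constant.

`simulate_screen` writes the summary dialect directly ("STERILE" or
"total, k NDJ") with one line per gene; the default planted truth uses
d = 0.10 and brood 400 for NDJ genes, comfortably inside the d ≥ 0.08,
brood ≥ 300 regime where the 1.7% threshold has essentially full power.

All generators consume a single `numpy.random.Generator`; identical
config and seed give byte-identical files.

## Numerical choices and problem sizes

* Thresholds live in one frozen `ScreenThresholds` dataclass serialized
  into every manifest; there are no hidden defaults in code paths.
* Test-bench problem sizes: 200 genes with 20 planted positives for the
  end-to-end recovery check; 2000 simulated broods of 300 per d value
  for estimator calibration; exhaustive oracle comparison of the
  hypergeometric tail for backgrounds up to N = 40. These sizes give
  Monte-Carlo standard errors well below the tolerances tested while
  keeping the default suite quick to run.
* Manifest timestamps differ between runs; reproducibility is judged on
  the output tables, which are byte-identical for identical inputs,
  thresholds, and seed.

## Known limitations

* The published end-of-funnel counts on the real expression atlas
  (1118 selected, 611 ovary-only) depend on unstated conventions
  (t-test variant, zero-variance handling, probe annotation vintage)
  and on the original data export, which is not packaged; the funnel is
  validated on planted synthetic data instead.
* The manual-review step of candidate selection has no reproducible
  rule; the package exposes explicit include/exclude lists instead of
  guessing.
* One stock id appears on two rows of the packaged screen table
  (GL00696); the fixture keeps both rows and pools them into one line
  call, and row-level counts are reported alongside.
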