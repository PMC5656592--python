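# Methods

## Model and rationale

Let x\_s ∈ R^G be the (linear-scale) expression profile of leukocyte
subtype s and let a bulk blood sample be m = Σ\_s p\_s x\_s with
proportions p on the simplex. For genes A, B, if x\_s[A] > x\_s[B] for
every s, then m[A] > m[B] for every p: within-sample orderings that are
unanimous across subtypes are preserved by any mixture. The pipeline's
contrapositive is its detection principle — a *reversal* of such a
reference ordering in a bulk sample implies expression change inside at
least one cell type. Orderings are also invariant to strictly increasing
per-sample transforms, so every stage of the pipeline is unaffected by
normalization choices, log scaling or monotone batch distortions; this
invariance is enforced by a dedicated test suite.

## Pipeline stages and their statistics

**Reference pairs.** A pair qualifies when one orientation holds in at
least `within_subtype_frac` of the samples of every purified subtype and
is the majority everywhere. The default is 1.0, the strictest reading of
cross-subtype stability; softer thresholds are available. A tied sample
(exactly equal values) supports neither orientation and therefore breaks
100% stability — a tie carries no ordering evidence. Enumeration is
O(G²) but runs in fixed-size row blocks, so memory stays
O(block × G).

**Control filtering** retains pairs whose reference orientation holds in
≥ `control_frac` (default 0.95, inclusive) of the study's control
samples. The denominator is all controls and ties count against
concordance — the conservative reading. Filtering removes orderings
fragile to age, sex and batch in the study population.

**Reversal detection** tests each filtered pair's 2×2 table
(control/case × concordant/reversed; ties excluded from both cells,
shrinking group totals). The default test is one-sided toward excess
case reversal, since the scientific question is directional; a two-sided
variant is available. The one-sided Fisher p is computed vectorially as
the hypergeometric upper tail of the case-reversed cell given the table
margins (algebraically identical to the conditional exact test, verified
against enumeration and `scipy.stats.fisher_exact` in the tests);
identical tables are deduplicated before evaluation so hundreds of
thousands of pairs are testable in seconds. BH adjustment runs over all
filtered pairs; a pair is flagged only if additionally its case reversal
rate strictly exceeds the control rate.

**DEG calling** uses a global urn: with N filtered pairs, K of them
reversed, a gene in n pairs of which k are reversed gets
p = P(X ≥ k), X ~ Hypergeom(N, K, n). The universe is all filtered
pairs (the "global urn"), matching the question "could this gene's
presence among reversed pairs arise by chance". Genes in zero filtered
pairs are excluded from the BH family. Direction is a majority vote of
reversal geometry: a reversed pair promotes its previously lower gene
("up") and demotes the previously higher one ("down"); exact ties are
"undetermined". The vote rule is this package's choice — the gene-level
direction is not identified by the urn model itself.

**Permutation nulls.** The label-shuffle null preserves group sizes,
re-runs the full reversal test per iteration and reports
p = #{null ≥ observed}/B; when no draw reaches the observed count the
report is "p < 1/B" (e.g. "p < 0.001" at the default B = 1000). Ties
between null draws and the observation count toward p: a draw equalling
the observation is not evidence of excess, and the strict-inequality
variant would report significance for a saturated statistic. Randomness
uses one seed with spawned substreams (`SeedSequence(seed).spawn(B)`),
so iteration i is reproducible regardless of execution order. The
random-gene-draw null draws size-matched gene lists uniformly from the
background and counts members with at least one recorded interaction
partner.

**Supporting tests.** Per-gene DE screening uses the classical
equal-variance two-sample t-test (Welch by flag); aging screening uses
closed-form simple OLS of expression on age with a slope t-test
(df = n − 2), both BH-adjusted at FDR 0.05. Set-overlap tests are exact
upper-tail hypergeometric with an always-explicit universe; direction
consistency is an exact one-sided binomial against 0.5 (the printed
floor "< 2.2e-16" seen in some published tables is a reporting
convention, not the attainable minimum — with 21 trials the smallest
possible value is 0.5²¹ ≈ 4.8e-7). The rank-sum comparison is exact for
combined n ≤ 20 without ties, otherwise the normal approximation with
tie correction (no continuity correction). AUC is computed from midranks
(Mann–Whitney identity), exact under ties.

**Signature scoring.** The reversed pairs of a discovery cohort form a
rank signature; a sample's score is the fraction of signature pairs in
the disease orientation (ties lower the score only). The published work
this follows does not specify a combination rule; the match-fraction is
the simplest rank rule consistent with the framework and is evaluated
threshold-free by AUC. Signatures transfer across cohorts without
renormalization; pairs missing from a target universe are dropped with
the retained fraction reported.

## Synthetic data generator

The generator is first-class, tested code and defines the conditions
under which the pipeline's operating characteristics are measured.

* **Purified profiles**: gene base log2 means ~ N(7, 1.5²) (typical
  normalized microarray intensity scale), per-subtype deviations
  ~ N(0, 0.3²), measurement noise N(0, 0.15²) on log2 (multiplicative
  log-normal intensities, CV ≈ 10%). Because gene spacing dominates
  subtype deviation, most pairs order consistently across subtypes,
  providing a large reference-pair pool whose identity is checked
  against brute-force enumeration in tests.
* **Mixing**: control proportions (0.35, 0.25, 0.20, 0.12, 0.08) over
  five subtypes (a neutrophil-dominated blood-like composition;
  truncated and renormalized for fewer subtypes); per-sample jitter is
  Dirichlet with concentration 300 (proportion sd ≈ 0.03 for the major
  component). The proportion-shift scenario moves cases to
  (0.50, 0.20, 0.14, 0.10, 0.06) — no cell-intrinsic change.
* **Planted DEGs**: 40 genes, |log2FC| ~ U(2, 3) with random sign,
  acting in the largest (35%-mass) subtype of case samples only. The
  magnitude is deliberately in the strong-alteration regime (4–8× in the
  affected cell type): an urn-model power analysis shows a gene needs
  roughly ten significant reversed pairs for gene-level significance,
  which requires the mixture-level shift (≈ 1–1.5 log2 at these
  settings) to exceed the minimum pair gap enforced by the 95% control
  filter. Weaker planted effects (|log2FC| ≈ 1, mixture shift
  ≈ 0.4 log2) are largely invisible to the pipeline — consistent with
  the method's documented insensitivity to subtle changes, and the
  reason the default sits where it does.
* **Aging effects**: 50 genes disjoint from the DEGs with log2 slopes
  ± U(0.01, 0.03) per year; ages uniform on [52, 90] (an elderly
  case/control cohort range). Slopes act additively on the log2 scale,
  the natural "expression units" of normalized intensity matrices.
* **Cohorts**: 50 + 50 by default — small enough that the full pipeline
  runs in a few seconds at 1,000 genes, large enough for the Fisher
  stage to reach BH-corrected significance over ~3×10⁵ pairs.

What the generator does **not** emulate: platform-specific probe
effects, correlated gene modules, heavy-tailed or count noise,
population structure in proportions, or missing data. Passing tests
therefore demonstrate the pipeline's behavior under the mixture model's
own assumptions, not performance on any particular clinical dataset.

## Numerical choices and degenerate inputs

* Gene identifiers compare as exact strings (whitespace-trimmed);
  numeric ids order as zero-padded strings so canonical pair storage is
  platform-independent. Pairs store gene\_a < gene\_b with orientation
  ±1; swapping storage order flips orientation, never stability.
* Probe-to-gene collapse defaults to the per-sample median across
  probes (robust, and least disruptive to within-sample orderings);
  keeping the max-mean probe is available. Rows with any missing value
  are dropped before analysis — ordering comparisons need complete
  pairs.
* Thresholds ("at least 95%", "at least `within_subtype_frac`") are
  inclusive, implemented with a 1e-12/1e-9 epsilon against float
  division error.
* Zero-variance genes in the t-test get p = 1 when group means agree
  (p = 0 when constant groups differ); constant expression in the aging
  regression gets slope 0, p = 1; an exact linear fit gets p = 0.
* BH is the standard step-up with capping at 1, validated against
  statsmodels and hand enumeration; it is order-invariant and monotone.
* All-zero Fisher tables, empty groups, empty signatures, constant age
  vectors and out-of-range fractions raise immediately, before any
  computation.

## Limitations

* Results at full biobank scale (10⁴ genes, ~5×10⁷ pairs) require the
  original purified-leukocyte and blood cohort datasets; the desk-scale
  synthetic studies here exercise every code path but do not reproduce
  dataset-specific pair counts, DEG identities or transfer AUCs. The
  pipeline streams pairs in blocks, so the O(G²) stage scales to such
  runs in time rather than memory.
* The hypergeometric urn treats pairs as exchangeable, but pairs sharing
  a gene are correlated; gene-level p-values are therefore approximate
  (the permutation null provides a calibration-free complement).
* The direction vote and the signature score are this package's
  documented choices where the underlying method leaves the rule open.
* The optional GEO series-matrix reader parses the expression table
  only; phenotype characteristics are not interpreted.
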