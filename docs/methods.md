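# Methods

## Scope and data model

The pipeline begins where variant calling and annotation end: its inputs
are a genotype matrix (minimal VCF 4.2, GT only; multi-allelic records are
split per alternate allele), an annotation table (gene symbol, functional
class, HGVS c./p., per-panel allele frequencies with "." for unreported),
case/control labels, GMT gene sets, a weighted PPI edge list, and external
cohort variant tables.  Coordinates are 1-based VCF convention and the
variant key is `chrom:pos:ref:alt`.  Alignment, calling, re-annotation,
population-stratification QC, and any live database query are out of scope.

## Variant qualification

A qualifying variant is deleterious-class — nonsense, missense,
splice-site, frameshift, or in-frame indel; "indel" is represented by the
frameshift/in-frame pair and splice-region effects are collapsed into
splice-site, since finer consequence terms add nothing to a carrier
indicator — and rare at the stratum threshold in *every* reference panel
that reports it.  An unreported panel frequency counts as rare: absence
from a large reference panel is itself evidence of rarity, and real
annotation tables carry many "." entries.  Qualification runs at two
strata, MAF < 0.001 and MAF < 0.01, with strict inequality, so the strict
set is provably nested in the loose one.  Which panels participate is
configurable (two, `exac` and `kg`, by default).

## Carrier collapsing

Carrier status is dosage ≥ 1 at any qualifying site of the gene; a missing
genotype counts as non-carrier (the conservative choice for enrichment in
either direction, and the only one that needs no imputation model).  The
per-gene 2×2 carrier table is tested with Fisher's exact test.  Two
conventions are implemented: the one-sided upper tail P(X ≥ a), which is
the default because it reproduces published collapsing tables of this
design exactly, and the two-sided minimum-likelihood sum.  For tables with
no control carriers and a handful of case carriers the two coincide, which
is why zero-cell rows are convention-robust anchors for validation.  The
odds ratio is the raw cross-product ad/bc without Haldane-Anscombe
correction; bc = 0 is reported NA rather than forced finite.  Significance
uses strict p < α with α = 0.05 by default; ties in any ranking are broken
by gene symbol so output order is a total order.

scipy's `fisher_exact` provides the hypergeometric computation; the test
suite verifies both conventions against an exact-fraction enumeration
oracle over all tables with margins into the hundreds, so the library call
is a checked implementation detail, not an assumption.

## Single-variant association

Marker QC removes variants with > 10% missing genotypes, pooled MAF < 1%,
or exact Hardy-Weinberg p < 10⁻⁴.  HWE uses the exact conditional test
(probability of the heterozygote count given allele counts, summing
configurations no more probable than the observed one), computed on cases
and controls pooled — one marker-wide filter, switchable to controls-only;
no installed library exposes this test, so it is implemented directly and
checked against full enumeration.  The allelic test is Fisher's exact on
the 2×2 allele-count table with two alleles per called sample, missing
genotypes shrinking the denominator; it defaults to two-sided, matching the
convention of standard GWAS toolchains.  λ_GC is the median observed 1-df
χ² quantile over its null median 0.455; it is a diagnostic output, not a
correction.  QQ output is a table of expected/observed −log₁₀ p pairs;
plotting is left to the caller.

## Pathway over-representation

Enrichment is the upper hypergeometric tail with the background defaulting
to the union of the loaded gene-set collection — the only universe
recoverable from a GMT file alone — and configurable to an explicit list.
Input genes outside the background are dropped with a logged count.  The
rich factor k/K is reported per pathway for bubble-chart style output.
Because over-representation services differ in correction method, the
method is a labelled parameter (BH default) recorded in each result; the
top-k cut (k = 30 default) sorts by corrected p with raw p and set id as
tie-breaks.  Which enriched pathways count as phenotype-relevant is an
explicit configuration input (`select_candidates` tags), never inferred.

## PPI ranking

Edges are undirected, canonically ordered, deduplicated, with self-loops
rejected and scores required in [0, 1].  Within each of the two membership
groups, edges are retained when the confidence score is strictly above the
threshold (0.4, "medium confidence") and both endpoints are members.  A
gene's node count is its degree in that induced subgraph and its total
score the sum of incident retained weights; mean = total/nodes is defined
only for positive degree, and zero-degree members are simply absent from
the group.  The combined rank key averages the two groups' totals (and node
counts), an absent group contributing zero while still dividing by two —
the only reading consistent with published rows in which a single-network
gene's combined score is exactly half its group score.  `prioritize`
attaches burden p-values and flags reference-panel genes, the route by
which a high-ranking reference gene can join the candidate list without
having been a collapsing candidate.

## External overlap validation

Matching is keyed on gene symbol plus normalized HGVS strings: whitespace
stripped (including around ">"), unicode dashes mapped to ASCII, and simple
one-letter protein substitutions widened to three-letter codes; the
normalizer is idempotent.  Each internal/external pair reports its
strongest level — protein-exact, then cDNA-exact, then gene-only.
Coordinate matching is deliberately not attempted because external tables
report different transcripts.  Phenotype-category enrichment statistics of
biobank summary interfaces are not reproduced; the report lists overlap
counts by label instead.

## Synthetic cohorts

The generator emulates the study conditions, not sequence data: 82 cases
and 100 controls by default, tens of genes with 1-5 rare sites each, cohort
site AFs uniform on [0.0002, 0.008] (per-gene carrier rates up to a few
percent, the range of most published collapsing rows), 70% of sites
deleterious-class.  Because the collapsing statistic consumes only carrier
status, carriers are simulated at the gene level: control carrier
probability q = 1 − Π(1 − af_i)² over the gene's deleterious sites, case
carrier odds multiplied by the planted odds ratio, and each carrier
assigned one site with probability proportional to site AF (homozygous with
probability equal to that AF).  Neutral sites fill in under Hardy-Weinberg
independently.  Reference-panel AFs are drawn independently of cohort AFs —
a case cohort can be enriched for a variant that is vanishingly rare in a
reference population — log-uniform on [10⁻⁵, 6×10⁻³] so both strata are
populated (~70% of rare sites pass the strict stratum), with 15% of entries
unreported and 5% of sites panel-common (AF 0.01-0.05) to exercise the
missing-AF and exclusion rules.  Genotype missingness defaults to 0.  All
draws flow from a single `numpy` generator, so identical config + seed
reproduces byte-identical bundles; the writers emit exactly the formats the
readers consume and round-trip is tested as identity.

What the generator does *not* model: linkage and haplotype structure,
population stratification, relatedness, site-level sequencing error, or
per-sample coverage variation.  Passing tests therefore demonstrate the
statistical machinery under the carrier model the collapsing test itself
assumes; they do not certify robustness to confounding that the design
delegates to upstream QC.

## Operating-characteristic studies

`wesprio.studies` packages two simulation designs at the target cohort
size.  The null calibration study uses 500 genes with 8 rare deleterious
sites each, cohort AFs uniform on [0.005, 0.04], giving carrier rates of
roughly 0.08-0.48 — the informative mid-range of a collapsing table; at
very low carrier rates the exact test's discreteness makes it visibly
conservative, which is a property of the test, not a defect of the
pipeline.  Under the two-sided convention the empirical type-I error at
α = 0.05 falls within the 95% binomial interval of 0.05 at this gene count,
and the null p-value CDF never rises above the uniform by more than the
one-sided KS bound — the correct uniformity statement for a discrete,
conservative exact test, whose p-values are super-uniform rather than
uniform.  The recovery study plants one gene at carrier OR 5 and control
carrier rate 0.05 among 19 null genes and runs 200 replicate cohorts; the
planted gene's nominal-significance rate is compared against the exact
power computed by summing the rejection region under independent binomial
carrier counts (`exact_rejection_rate`), and its strict rank-first rate is
reported.  These sizes (500 genes, 200 replicates) keep each study to a few
seconds while leaving the binomial standard errors around 0.01-0.02.

## Numerical and degenerate-input choices

Fisher and hypergeometric tails come from scipy and are clipped to [0, 1];
equality tests against printed values use the printed precision
(half-last-digit tolerance).  One published combined-network row disagrees
with the average of its own printed per-group totals by 0.003 — a rounding
slip in the source table — and is checked at that looser tolerance.  Empty
inputs return empty outputs (λ_GC is None and flagged); all-zero HWE input,
empty gene-set, empty background, non-positive sample counts, and
odds ratios on zero denominators raise or return NA rather than guessing.
Reports contain no timestamps, so identical inputs give byte-identical
output.
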