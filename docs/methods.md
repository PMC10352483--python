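# Methods

## Data model

A proximity barcoding assay read is a fixed-offset concatenation
`EV tag | protein tag | molecular tag (UMI)`. Tag lengths are
configuration, not inference: defaults are a 15 nt EV tag, an 8 nt protein
tag (set by the panel file) and an 8 nt UMI, giving 31 nt reads. The
decoder's unit of evidence is the distinct (EV tag, protein, UMI) triple:
after quality filtering and tag assignment, `count(EV, protein)` is the
number of distinct UMIs observed for that pair. UMIs are identical only if
byte-identical — no UMI clustering — and EV tags are matched exactly (EV
barcodes are random-mers, not a whitelist, so error-correcting them has no
sound reference set). Protein tags may optionally be matched within a
Hamming radius when the nearest panel tag is unique; equidistant ties are
dropped and counted.

"Quality score < 20" is interpreted strictly as the minimum per-base Phred
over the read; a mean-quality mode is available
(`LayoutConfig.quality_mode`). Rows of the per-sample EV × protein matrix
are ordered by first appearance of the EV tag; columns follow the panel
order; internal indices are 0-based.

## Synthetic generator

The generator emulates a two-group ascites screen: each group's EVs are a
mixture of subpopulations; each subpopulation is a vector of per-protein
detection probabilities (plus a 0.01 nonspecific baseline across the
panel); a protein present on an EV receives a zero-truncated Poisson
molecule count (rate 2 by default, so UMI deduplication is exercised).
Defaults are chosen to mirror the magnitudes of the motivating assay:

- 113-protein panel, led by the named ascites-EV markers (CDCP1, TACSTD2,
  EPCAM, ERBB2, ITGA3, ITGA6, ITGB1, ITGB4, EGFR, LAMP1, CD151, CD9, CD63,
  CD81, ITGAL), with numbered placeholders for the remainder; tags are
  drawn with pairwise Hamming distance ≥ 3 so single-mismatch correction
  is always unambiguous.
- 8 case vs 18 control samples; 20,000 EVs per sample by default
  (the reference study in `evscope.study` uses 5,000 to keep desk-scale
  runtimes, and tests use less still).
- three background subclusters shared by both groups (tetraspanin-rich,
  integrin-rich, dim), tuned so the median detected proteins per EV lands
  at ≈ 3–4; one case-only tumour subcluster carrying the marker set above.
- reads per molecule = 1 + Poisson(rate − 1) with default rate 1.2 (mild
  PCR duplication; every molecule yields at least one read); substitution
  errors at 0.001 per base; 5% of reads emitted below Q20.

Molecules of one (EV, protein) are assigned *distinct* UMIs by
construction, so at zero error rate and zero low-quality fraction decoding
reproduces the truth matrix exactly — this round-trip identity anchors the
decoder tests. The quality model is deliberately two-valued (Q40 pass /
Q12 fail) because only the Q20 filter matters downstream; no full Phred
error model is attempted. EVs on which no protein is detected are dropped
(invisible to the assay), so realized EV counts fall slightly below the
nominal count. Not emulated: amplification bias, indel errors, EV-tag
collisions (doublets), sample contamination, or antibody cross-reactivity
— so passing tests demonstrate the statistical machinery, not robustness
to those real-data artifacts.

## Normalization and differential testing

Raw expression of a protein in a sample is the sum of its molecule counts
over all EVs. Between-sample normalization follows the canonical TMM
recipe: the reference sample is the one whose upper-quartile count
fraction is closest to the mean; per sample, M (log2 ratio) and A
(average log2 abundance) values over proteins positive in both sample and
reference are trimmed — 30% of each M tail, 5% of each A tail — and the
factor is 2 to the inverse-variance-weighted mean of the surviving M
values; factors are rescaled to geometric mean 1. A unit test pins the
implementation to factors computed by an established reference
implementation on a frozen 113 × 6 fixture (agreement ≤ 1e-6). Note the
precision weights depend on library size, so factors are only approximately
invariant to depth-scaling one sample (≈ 0.1% on realistic fixtures); the
exact-invariance case (a sample pair differing only in depth) yields
factors of exactly 1. Normalized values are counts per million of the
effective library size (library size × factor).

Two-group testing per protein uses the adaptive tree: Shapiro–Wilk
normality in each group, then an F-test of variance homogeneity, with
α = 0.05 at both gates (the gate level is a choice; the source procedure
names the tests but not the threshold). Either group non-normal →
two-sided Mann–Whitney U; normal but heteroscedastic → Welch's *t*;
otherwise Student's *t*. Mann–Whitney is implemented in-repo: the exact
null distribution by enumeration of all rank splits of the pooled midranks
(so ties are handled) when both groups have ≤ 8 observations — matching
the 8-patient case arm — and a tie-corrected normal approximation with
continuity correction otherwise. Benjamini–Hochberg is implemented as the
plain step-up rule; proteins constant in both groups are flagged
`undefined` and excluded from the BH family. A constant group is treated
as maximally non-normal (Shapiro–Wilk p set to 0), routing to the rank
test. Tests are two-sided throughout. Differential testing defaults to
TMM-normalized values (`use_normalized=False` toggles raw), and the pair
(combination) analysis reuses the same machinery on per-sample CPM values,
excluding pairs observed in fewer than two samples.

## Co-expression pairs

A pair (A, B) is counted once per EV carrying ≥ 1 molecule of both
proteins (the detection threshold is configurable); the count is the upper
triangle of BᵀB for the binary detection matrix. CPM normalizes by the
sample's total pair observations — the conventional per-column scaling —
not by EV count. Only pairs (k = 2) are considered.

## Clustering

Pooled EVs are embedded as binary detection vectors by default: single-EV
counts are shallow and the cluster read-out is detection frequency; raw
and log1p count modes are retained. The SOM is a batch implementation:
prototypes initialized from distinct data rows under the seed; each epoch
maps every EV to its best-matching unit (Euclidean; exact ties go to the
lowest node index) and replaces each prototype with the Gaussian
neighborhood-weighted mean of the node sums; the neighborhood σ decays
geometrically from max(grid)/2 to 0.5 over 10 epochs. Grid 10 × 10 and
k = 28 are the defaults (k = 20 in the scaled reference study); both are
flags. Metaclustering is average-linkage hierarchical clustering of the
occupied nodes' prototypes cut at k (optionally consensus-averaged over
node-subsampled replicates); unoccupied nodes inherit the nearest occupied
prototype's label; metacluster ids are renumbered 1..k by descending EV
membership. Whether a fixed k or an elbow criterion produced the original
28 clusters is not documented anywhere we could rely on; fixed k is the
deterministic, auditable choice. Cluster group enrichment uses a
two-sided binomial test of member case-group counts against the pooled
case fraction, BH-corrected across clusters. No per-sample batch
correction is applied. A 2-D embedding for plotting can be attached from
any external routine; it carries no analytical weight and is not
implemented here.

## ROC

Scores are sample-level (the cohort n matches the 8 + 18 design):
normalized expression for a single protein; for a pair, either the
sample's CPM of the co-expression pair (default — it uses the assay's own
combination statistic) or an in-sample logistic composite of the two
normalized expressions. AUC is the tie-corrected concordance
U/(n₁n₂); the empirical curve is swept over all distinct thresholds and
its trapezoidal area equals the concordance to 1e-12 (property-tested).
Orientation is chosen so AUC ≥ 0.5, with the flip reported. Performance
is apparent (resubstitution); no cross-validation or optimism correction
is attempted, and no DeLong intervals are required.

## Clinical statistics

The IHC product score is intensity (0–3) × positive-cell percentage bin
(1–4), dichotomized low (0–4) / high (5–12); exactly the products
{0, 1, 2, 3, 4} are low. Association with ordinal clinicopathological
variables expands the contingency table to per-patient pairs, codes
expression low < high and clinical categories ascending (this single
convention reproduces all six published coefficients, including the
negative M-stage value), assigns midranks within ties, and takes the
Pearson correlation of midranks; p is two-sided from
t = rs·√(n−2)/√(1−rs²) on n−2 df — the t approximation is consistent with
the published p-values, and an exact permutation test at n = 79 would add
nothing. Patients with a missing value for a variable are excluded
listwise for that variable (hence the 78/75/79 per-variable totals in the
bundled table). Kaplan–Meier estimation and the log-rank test are
delegated to lifelines behind the module's interface (standard
hypergeometric-variance log-rank, no continuity correction); both are
verified against hand-rolled product-limit and observed-minus-expected
oracles in the tests. The ELISA helper fits OD against log10
concentration (or a four-parameter logistic) and inverse-predicts sample
concentrations, flagging ODs outside the standards' range as
unquantifiable.

## Problem sizes and determinism

The reference synthetic study (`evscope.study`) runs 8 + 18 samples at
5,000 EVs each through simulate → FASTQ → decode → cluster; the recovery
acceptance test repeats it for seeds 1–10 and requires ≥ 9/10 seeds to
yield a metacluster with ≥ 90% case-group composition whose top-10
detection markers include the full planted set. The type-I error check
simulates 500 null replicates of a 20-protein panel. All stochastic
stages consume a single integer seed; fixed seeds give byte-identical
FASTQ output and identical clustering, and the workflow manifest records
seeds and parameter hashes so reruns are comparable.

## Known limitations

- The generator's independence assumptions (proteins independent given
  the subcluster; EVs i.i.d.) understate the correlation structure of
  real vesicle populations; recovery results on synthetic data are
  necessarily optimistic (synthetic AUCs saturate at 1.0, whereas the
  real-data analogues are < 1).
- EV-tag doublets/collisions are not simulated and the decoder does not
  attempt doublet detection.
- Multi-group designs, covariates, moderated (empirical-Bayes) tests, Cox
  regression and k > 2 marker panels are out of scope.
- The workflow `run` stages cover the sequencing pipeline
  (simulate → … → roc); the clinical analyses consume clinical tables,
  not pipeline outputs, and run through their own entry point.
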