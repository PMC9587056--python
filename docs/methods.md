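# Methods

## Study design emulated by the generator

The synthetic-data module reproduces the structure of a hypothesis-driven
transcriptomic screen in a non-model amphibian: five treatment groups
(solvent control plus two organophosphorus pesticides at 6 h and 24 h)
in duplicate, each annotated gene represented by 1–5 assembled transcript
fragments (about 2–3 accepted per gene on average, Dirichlet(5) share
split so fragments stay informative repeats), and integer counts drawn
from a negative binomial with variance μ + φμ².

Defaults and what they mean:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 2000 | annotated genes |
| `fragments_per_gene` | (1, 5) | uniform fragment count per gene |
| `n_replicates` | 2 | biological replicates per group |
| `baseline_log_mean`, `baseline_log_sd` | 5.5, 1.5 | log-normal gene abundance (median ≈ 245 counts) |
| `nb_dispersion` φ | 0.05 | biological CV ≈ 22 % at high counts |
| `library_size_cv` | 0.2 | log-normal library-depth variation |
| `frac_affected` | 0.3 | non-HK genes with a nonzero effect |
| `down_up_ratio` | 3.0 | probability ratio of down- vs up-regulation |
| `effect_log2_range` | (0.3, 2.0) | planted \|log2 FC\|, i.e. mostly < 2-fold with a tail to 4-fold |
| `n_hk_genes` | 50 | designated housekeeping genes |
| `hk_cv_target` | 15 % | ceiling the HK genes are tuned under |
| `frac_bad_fragments` | 0.25 | corrupted fragments (≈ the fraction a real funnel rejects) |

An affected gene receives one signed log2 effect applied to all four
treated groups; this is a simplification (real responses differ by
compound and time) that keeps the per-pair ground truth unambiguous.
Housekeeping genes get zero effect, a high abundance floor and a
tightened dispersion φ_hk = min(φ, (0.45·target/100)²) so that most
realize CV% below the target; they are excluded from corruption. The
candidate reference panel (group tag `A`) contains the true HK genes
plus an equal number of treatment-responsive decoy genes — emulating an
a-priori proposed panel of which some members turn out unstable. Other
genes carry pathway tags B–E (40 % of non-HK genes) or `none`.

Corruption takes two forms, matching the qualitative filter it must
exercise: a dropout (one sample forced to zero) or an erratic fragment
(all counts rescaled below the low-expression floor, one replicate then
multiplied by Uniform(0.05, 0.3)). One top-level seed feeds five labelled
substreams (structure, counts, corruption, hits, qPCR), so regenerating
one artifact never perturbs another and every output is bit-reproducible.

What the generator does **not** emulate: mapping ambiguity between
fragments, compound- or time-specific effect profiles, correlated
library composition biases, batch effects, and gene-length effects.
Passing the recovery studies therefore demonstrates the statistical
machinery under the declared model, not performance on any real dataset.

## Curation

Stage 1 (annotation): a fragment's best hit is the row with the highest
bit score, ties broken by lower e-value then lexicographic subject id —
fixed so reruns are deterministic. Confirmation requires the best hit to
point at the annotated gene with percent match strictly above the
threshold (default 50). Whether "match" means identity or coverage in
the original screen is not specified anywhere we could rely on; the
implementation treats the column it is given as the percent-match value
and only fixes the threshold semantics.

Stage 2 (expression): a fragment is rejected if any sample value is
exactly zero, or if its overall mean is below `low_floor` (default 5
TMM/CPM units) while some within-group CV% exceeds `erratic_cv_percent`
(default 50). The conjunctive rule operationalizes "very low and
erratic"; both knobs are config-exposed because they are conventions,
not estimates.

## TMM normalization

Implemented from the published recipe: reference sample = the one whose
75th-percentile count fraction is closest to the mean of those; per-row
M and A values over rows positive in both samples; double trim (30 % of
each M tail, 5 % of each A tail, rank-based); weights equal to the
reciprocal of the asymptotic variance (N−y)/(Ny) + (N_r−y_r)/(N_r y_r);
factor 2^(Σ wM / Σ w); factors rescaled to geometric mean 1. Normalized
abundance is counts per million of the effective (factor-adjusted)
library. A sample sharing no positive row with the reference is an
error naming the sample.

## Reference-gene statistics and standardization

Stability statistics per transcript (mean, min, max, SD, median, CV%)
are computed over all samples of all treatments; SD uses the n−1
denominator (at n = 10 the published worked examples are consistent with
either convention; n−1 is the statistical default here). Selection keeps
CV% strictly below the ceiling (default 20 %); strict vs non-strict is
config-irrelevant for the published panel, and strict was fixed.

Standardization: for each HK transcript h, r_{h,s} = E_{h,s} /
mean_control(E_h); the per-sample factor F_s is the arithmetic mean over
h; standardized expression is E/F_s and the relative table reports
mean_t/mean_control per row. The factors are per sample by default so
duplicates keep independent variation; a per-treatment mode (factors
averaged over each group's replicates) is available behind a flag
because "averaged for each treatment" admits both readings. By
construction the mean factor over control samples is exactly 1, and HK
relative expression averages to 1 per treatment.

## Exact nonparametric tests

Observations per gene are the accepted fragments × replicates per
group, treated as exchangeable repeats. The Kruskal–Wallis H uses
midranks and the tie-correction factor 1 − Σ(t³−t)/(N³−N); Mood's
median test dichotomizes at the grand median with ">" vs "≤".

p-values: full enumeration of all N!/Πnᵢ! rank assignments when total
N ≤ `exact_limit` (default 10; the enumeration null depends only on the
rank multiset and group sizes and is LRU-cached across genes), otherwise
a seeded Monte-Carlo permutation null (default 100 000 draws for the
single-test functions, 10 000 in the matrix driver; p = (1+hits)/(1+B)),
otherwise a chi-square approximation flagged in the result. The median
test's exact p sums multivariate-hypergeometric table probabilities ≤
the observed one over tables with fixed margins. Pairwise
treated-vs-control tests are the two-group case (equivalent to the exact
two-sided rank-sum); the pairwise enumeration limit is raised to N ≤ 14
since C(14,7) is tiny.

Calls use the two-tier scheme seen in practice: significant at p ≤ 0.05,
tendency at 0.05 < p ≤ 0.10 (direction suppressed above that), with
fold-change bins on max(R, 1/R): < 2-fold, 2–4-fold, > 4-fold. Permuted
statistics are compared to the observed one with 1e-9 absolute slack so
ties in H count as extreme. No multiple-testing correction is applied —
the workflow reports raw exact p-values per gene by design.

## Collapsed-gene NB exact test

Fragments are summed into gene counts (the "collapse"), deliberately on
the raw, unfiltered matrix — mirroring the screening convention this
route represents. The common dispersion is a method-of-moments pool:
counts rescaled to the geometric-mean effective library, per-gene
within-group means and variances averaged over replicated groups,
φ_g = max(0, (s²−m)/m²), and the median over genes with mean > 5. This
estimator is simple and slightly conservative (it recovers φ = 0.1 as
≈ 0.085 in calibration runs and ≈ 0 for Poisson data); exact numerical
agreement with quantile-adjusted conditional-likelihood estimators of
dedicated DE packages is not a goal.

The exact test rescales each sample count to the pair's geometric-mean
effective library (rounding half-up, deterministically), conditions on
the pooled total T with group sums modeled NB(nᵢμ̂, dispersion φ/nᵢ),
and sums the conditional probabilities of all splits of T as or less
likely than the observed one. log2 FC uses a library-size-proportional
prior count (default 0.5), which reduces to (S₁+½)/(S₂+½) for equal
libraries and makes the statistic antisymmetric under label swap. DEG
calling is the classic joint rule (FC ≥ 2 or ≤ ½ and p ≤ 0.05); ranking
is by descending |log2 FC| with ties broken by smaller p then gene id,
binned at ranks 10/50/100/500/1500.

## Concordance, heat map, qPCR

Concordance counts a gene × pair cell as agreeing when both approaches
call a significant change in the same direction or both call nothing;
tendencies count as not-called unless a flag says otherwise, and the
direction requirement can be relaxed — both conventions are exposed
because the comparison convention is a choice, not a fact. The summary
reports overall and per-pair percent agreement and the histogram of
genes by number of agreeing pairs.

qPCR: quantities Q = E^(−Ct) with per-gene efficiency E (default 2.0;
efficiencies are inputs, never estimated — poorly calibrated assays are
the caller's responsibility to exclude), per-sample normalization factor
= geometric mean of HK quantities, fold change = ratio of geometric
means of normalized quantities against control. Technical replicates
are averaged on the Ct scale first. With one HK gene and E = 2 the
method collapses to classic 2^−ΔΔCt, which the tests verify; adding any
per-sample Ct constant cancels exactly.

## Validation studies and problem sizes

The `evaluation` module runs the recovery studies used by the test suite
and the reproduction script: reference-panel worked examples (12
transcripts), annotation confirmation on 225 single-fragment genes,
housekeeping recovery/false-admission on the default 2000-gene design
(selection by each panel gene's most stable accepted fragment),
detection of effects pinned at 4-fold (NB call in the right direction,
with the nonparametric pairwise test at p ≤ 0.10 as fallback), the
down:up call balance among genes with planted effects under the 3:1
simulation, and qPCR recovery over 100 replicate noisy assays
(Ct SD 0.2). These sizes keep a full run around half a minute while
leaving every estimate's sampling error well inside the margins being
asserted. The down:up balance is measured among genes with planted
effects because under 30 % prevalence and n = 2 the null calls of the
unaffected majority would otherwise dilute the observed ratio toward 1
— a property of small designs, not of the calling rules.

## Known limitations

- Fragments are exchangeable repeats within a gene; no per-fragment
  weighting, so a gene's largest fragment dominates its pooled relative
  expression.
- Common dispersion only — no tagwise/trended dispersion, no GLM or
  quasi-likelihood route, no FDR-based calling.
- The NB exact test's library equalization uses deterministic
  rescale-and-round rather than quantile adjustment of the full count
  distribution.
- qPCR efficiencies are taken at face value; no standard-curve fitting
  or melt-curve QC.
- Monte-Carlo p-values have resolution 1/(B+1); for calling at the 0.05
  and 0.10 tiers the default draws are ample, but exact reproduction of
  tiny p-values requires the enumeration regime.
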