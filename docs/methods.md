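# Methods

`kitox` implements a clinically weighted transcriptomic-signature analysis
for kinase-inhibitor (KI) cardiotoxicity: clinical risk scores are derived
from spontaneous adverse-event reports, drug perturbation profiles from
cardiomyocyte differential-expression tables, and the two are joined by a
bootstrap-stabilised elastic net that selects a sparse predictive gene
signature. Chemical-structure and kinase-binding analyses situate the risk
scores in compound space. This note records the models, the parameters that
matter, and the design choices made where the procedure was genuinely open.

## Clinical risk: reporting odds ratios

For one drug and one adverse-event group, reports are tallied into a 2x2
contingency: f_dt (drug, target events), f_dn (drug, other events), f_nt
(all other drugs in the table, target events), f_nn (other drugs, other
events). The reporting odds ratio and its delta-method uncertainty are

    ROR = (f_dt / f_dn) / (f_nt / f_nn)
    SE(log ROR) = sqrt(1/f_dt + 1/f_dn + 1/f_nt + 1/f_nn)
    95% CI = exp(log ROR +/- 1.96 * SE)

Choices:

* **Risk-score scale.** The regression target is the natural-log ROR —
  symmetric around 0 and the scale on which the SE is defined. A raw-ROR
  target is available via `raw_ror_score=True`.
* **Comparator class.** All other drugs in the supplied table. Restricting
  the table restricts the reference class; this is deliberate (the class of
  "all other kinase inhibitors" is whatever the table holds).
* **Zero cells.** Hard error by default, naming the offending cell; the
  Haldane–Anscombe +0.5 correction is behind an explicit flag. The CI
  coverage simulation in the tests (2,000 replicates, expected cell counts
  >= 20) confirms 95% nominal coverage within [93%, 97%].
* **Event grouping** is a flat included-minus-excluded term list, not an
  ontology engine. Term lists are user-supplied configuration.
* **Ranking concordance** between two databases' risk rankings uses the
  Spearman rank correlation. Phenotypic-assay concordance flags a drug when
  its fractional readout change strictly exceeds 0.20 ("more than 20%") and
  reports a rank-biserial association between flags and risk ranks.

## Expression profiles

Per-cell-line differential-expression tables (log fold-change + p-value per
gene per drug, as produced by a count-based DGE fit such as edgeR) are
collapsed per drug by the **per-gene median across available cell lines**
(3 or 4 lines, NaN-skipping). The representative p-value is the median
across lines (Fisher combination available by flag); the source tables
aggregate fold-change by median, and median-of-p keeps the two summaries
symmetric.

Top-N gene lists are ranked by ascending p-value or descending |median
fold-change|, with ties broken by larger |FC| then lexicographic gene id —
deterministic across platforms, and prefix-stable in N. Jaccard indices
J(A,B) = |A∩B|/|A∪B| compare the lists across drugs. PCA operates on the
drugs x genes matrix of **absolute** median fold-changes, column-centered
but not variance-scaled (unscaled preserves effect magnitudes). Tissue
similarity compares a drug's top-500 set with per-sample top-gene sets,
ranking tissues by descending median Jaccard; top-250 is selectable where a
smaller list is preferred.

## Enrichment and risk correlation

Per-drug top-250 (by p-value) gene lists are tested against a gene-set
library by the one-tailed Fisher exact test: p is the upper hypergeometric
tail P(overlap >= observed) given the universe, set and query sizes. Terms
are then correlated with the per-drug risk scores across drugs: the default
statistic is **-log10(enrichment p)** (strong enrichment maps to large
positive values; raw-p is available by flag) and the default correlation is
Pearson (Spearman selectable). A term passes the screen when its minimum
enrichment p across drugs is < 0.05 and |r| > 0.25; no multiple-testing
correction is applied at the screen (a Benjamini–Hochberg helper is
provided for transparency). Disease terms are removed by a user-supplied
blocklist rather than a hardcoded list.

A note on null calibration: the exact test is discrete and therefore
super-uniform — with small margins the attainable size sits well below the
nominal level (e.g. 0.021 for universe 400, set 40, query 30). The null
rejection-rate checks therefore use margins with fine-grained overlap
support (universe 1,000, set 200, query 100; attained size 0.047), where a
~5% null rate is actually achievable.

## Two-stage signature regression

Input: X (drugs x genes, median log fold-changes) and y (per-drug log-ROR
risk). Two drugs are split off for external validation (~10% at the study's
23 drugs); the rest train the signature.

**Elastic net.** Predictors are standardised internally; the objective is
(1/2n)||y − b0 − Xb||² + λ(α||b||₁ + (1−α)/2·||b||₂²). α defaults to 0.5
(equal L1/L2 mix); λ is chosen by 5-fold cross-validation over a 50-point
log grid unless fixed. The λ=0 and α=0 limits are solved in closed form
(OLS / ridge) and verified against independent closed-form oracles in the
tests.

**Stage 1 — stability selection.** B bootstrap resamples of the (profile,
risk) pairs (B=1000 by default; resamples with fewer than 3 distinct drugs
are redrawn and logged). Each resample is fit with a CV-chosen λ; genes
with nonzero coefficients are recorded together with a scaled coefficient:
|standardised coefficient| divided by the within-bootstrap maximum (range
[0,1]). Per gene this yields the selection frequency φ, the mean scaled
coefficient c̄ over the bootstraps where it was selected (0 if never), and
the importance I = φ·c̄ — zero exactly when a gene is never selected. An
sd-scaled alternative (raw |standardised β|) is behind `scale="std"`; which
scaling the original procedure used is not recorded, so both ship.

**Stage 2 — percentile sweep.** For each percentile q in the grid, the
candidate set is all genes with importance **strictly above** the q-th
percentile of the importance distribution, computed with the `'higher'`
order statistic. Under this convention 99.755% of 10,749 distinct values
retains exactly 26 genes (the linear-interpolation quantile would retain
27). Each candidate set is scored by leave-one-drug-out RMSE; q* is the
argmin, ties resolved toward the larger (sparser) percentile; q=0 keeps
every gene; an empty candidate set is scored as the intercept-only model.
Within the LOO loop, λ is selected once per candidate subset by 5-fold CV
on the full training set, then each fold refits coefficients at that λ —
re-running λ-CV inside every fold of a 21-drug set would be both unstable
(n=20 folds) and ~20x slower, and the original procedure does not specify
it. Selection (stage 1) is likewise not re-run per fold: the sweep scores
subsets of one fixed importance ranking, as the two-stage sequencing
implies; fully nested reselection is out of scope.

The final model refits the elastic net on the full training set restricted
to the winning subset; variable importance is |standardised coefficient|
normalised to max 1. The stored model (genes, coefficients, per-gene
standardisation, α, λ, q*) reproduces its predictions exactly from JSON.
Drug-exclusion sensitivity reruns sweep + refit without each training drug
in turn (reusing the stage-1 summary) and reports the change in best
cross-validated RMSE.

## Chemistry and binding profiles

* **Weighted Tanimoto.** Four fingerprint channels — circular radius-2
  (ECFP4-like, 2,048 bits), circular radius-1 (ECFP2-like, 2,048 bits),
  path-based ("Daylight-like"), key-based (MACCS-like, 166 keys) — averaged
  with weights 0.30/0.30/0.30/0.10. The core consumes precomputed
  fingerprints from a plain-text format; an optional rdkit adapter
  fingerprints SMILES.
* **SAS map.** All unordered pairs scored as (weighted Tc, DCS = |risk_i −
  risk_j|). The similarity threshold defaults to the 90th percentile of the
  pairwise Tc distribution (the "top 10%" rule; fixed values such as 0.35
  or 0.38 can be supplied instead); the DCS threshold defaults to half the
  maximum DCS. Strict ">" assigns the high side, so pairs exactly at a
  threshold fall low/left. Quadrants: upper-left (dissimilar, large ΔCS),
  lower-left, lower-right "smooth SAR", upper-right "activity cliff".
* **Selectivity.** score = (#kinases with Kd <= 500 nM) / (#assayed), in
  [0,1]; near 1 is promiscuous. The source data ship no explicit formula
  for this score, so the fraction-of-panel definition is a package choice,
  flagged here; unassayed kinases are excluded from both counts.
* **Kd heat-map transform.** −log10(Kd/1e5) with Kd in nM — the divisor is
  the only reading of "scaled by 100,000" that keeps nM-scale values
  non-negative; base and divisor are configurable.
* **Clustering.** Agglomerative, average linkage, on distance 1 − Tc, with
  lexicographic input order so ties resolve deterministically; trees are
  exportable as Newick.

## Synthetic studies

The generator emulates every pipeline input with known ground truth.
Defaults mirror the study shape: 23 drugs, 4 cell lines, 6 replicates,
2,000 genes of which 10 carry signal, a 242-kinase panel, risk truth
uniform on [−1, 2].

* **Expression.** For signal gene g and drug d, each replicate draws
  β_g·r_d + Normal(0, noise_sd); null genes are pure noise. Cell-line
  tables hold the replicate mean and a one-sample t-test p — p-values are
  computed from the same replicates as the fold-changes, so p-rankings and
  FC-rankings correlate as in real DGE output. Signal slopes default to
  magnitudes 1–2 with alternating signs; noise_sd defaults to 0.5, giving a
  realistic but comfortably detectable signal at the default replicate
  count. All draws flow through substreams keyed by (seed, stream, entity),
  so enlarging the gene panel never perturbs drug-level draws.
* **Reports.** Each drug files `reports_per_drug` reports; target-event
  counts are binomial with odds = true ROR x background odds. A
  deterministic comparator pseudo-drug (`OTHER_KI_POOL`) carries
  `comparator_reports` reports at exactly the background odds, fixing the
  reference class so the per-drug ROR estimated against the pool is
  consistent for the configured truth. Background odds default to 0.1 —
  a grouped heart-failure event class at ~9% of a cardiotoxic drug class's
  reports — which by the delta-method SE makes the estimator's error at
  1e5 reports/drug small (SE ≈ 0.011 in log-ROR).
* **Chemistry.** Fingerprints derive from cluster prototypes by per-bit
  mutation (within-cluster similarity exceeds between-cluster in
  expectation). The Kd matrix is built from a latent promiscuity score
  constructed to correlate with the risk truth at exactly the configured
  in-sample Pearson r (0.7 by default); bound kinases draw Kd log-uniform
  in (1, 500] nM, unbound in (1000, 1e5] nM.

What the generator does **not** emulate: read-level sequencing noise,
library-size effects and normalisation artefacts, gene–gene correlation
structure from pathways, confounded reporting (demographics, polypharmacy,
stimulated reporting), or real chemical-space geometry. Passing tests
demonstrate that the estimators recover the truth under the assumed model,
not that the biological signal in real data has this structure.

## Numerical conventions

* Floats are written to TSV/JSON with 12 significant digits; identical
  config + seed reproduces byte-identical outputs (checksummed in the run
  manifest).
* Seeds are expanded into named per-stage substreams (hash-derived, below
  2^31); the whole two-stage regression is bit-reproducible under a fixed
  seed and invariant to row/column order (resampling indexes a canonically
  sorted drug list).
* Coordinate-descent tolerances: 1e-8 for single fits (closed-form limit
  checks at 1e-8 depend on it), 1e-4 inside λ-CV where only the argmin
  matters.
* Degenerate inputs: zero-variance predictors are dropped with a warning;
  zero-variance replicate sets in the noiseless limit map to p=0 (nonzero
  mean) or p=1; empty candidate sets score as intercept-only; all-zero
  fingerprint pairs have Tc defined as 0 with a warning.

## Problem sizes in the shipped checks

The test suite and acceptance script run the full two-stage procedure at
2,000 genes / 23 drugs / B=200 bootstraps — large enough for stable
selection frequencies and a sparse recovered signature, small enough for a
single-CPU run in minutes. The stability stage is the dominant cost and is
linear in B; the published-scale configuration (~10,700 genes, B=1000) uses
the same code path.

## Known limitations

* The per-bootstrap λ rule (CV-chosen) and the coefficient scaling are
  assumptions where the original procedure is silent; both alternatives are
  flagged or shipped.
* The enrichment screen correlates -log10 p by default; correlating raw p
  flips signs but is otherwise supported.
* The ROR model has no confounding adjustment (no age/sex/indication
  strata) and implements no disproportionality statistics beyond the ROR.
* Binding modes (type I/II/...) are pass-through labels, not computed.
* The tissue-similarity operation is generic over any supplied tissue
  table; no expression-atlas download is included.
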