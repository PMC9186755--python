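# Methods

## The model

`iotnl` scores a tumor's capacity to provoke immune elimination from its
clonal architecture. The premise: a tumor is a mixture of clones, and a
clone whose neoantigens have already been edited/tolerised (immune escape)
contributes nothing to immunogenicity, however many neoantigens it carries.
The patient score therefore restricts the neoantigen load to clones still
in the elimination stage and weights each clone by its cellular prevalence:

    editing_score_i = load_i / n_nonsilent_i
    stage_i         = escape  if editing_score_i > cutoff else elimination
    ioTNL           = Σ_{i ∈ elimination} load_i · CCF_i

where `load_i` is clone *i*'s neoantigen count, `n_nonsilent_i` its
non-silent mutation count and `CCF_i` its cancer cell fraction. TNL
(`Σ load_i` over all clones) and TMB (non-silent mutations per Mb) are
computed alongside as comparator biomarkers.

The chain from raw calls to the score is: read-level variant filtering →
CCF estimation per mutation → clone clustering → per-clone editing score
and staging → patient score → cohort statistics.

## Variant filtering

Candidate somatic SNVs pass only if all eight criteria hold: tumor and
normal depth ≥ 10×; tumor VAF ≥ 5% with normal VAF < 2%; ≥ 3 supporting
reads; > 10 bp from the nearest other candidate on the chromosome;
mutant-read mapping qualities significantly above 30 (p < 0.2) and base
qualities significantly above 20 (p < 0.05); no enrichment of the variant
near read ends (p threshold 0.1); and a significant tumor-vs-normal
allele-count contrast (two-sided Fisher, p < 0.05). InDels pass at tumor
VAF ≥ 10% and no germline evidence.

Two constructions were genuinely open and are resolved as follows:

* *Quality-vs-constant tests.* A two-sample rank-sum test against a scalar
  threshold is undefined, so criteria V/VI are one-sided Wilcoxon
  signed-rank tests on (quality − threshold), zero differences dropped
  (Pratt handling available), exact null for n ≤ 25 when well defined and
  a tie-corrected normal approximation otherwise. An empty evidence list
  fails the criterion (tallied as `insufficient_evidence`) rather than
  erroring the batch.
* *Read-end enrichment.* Criterion VII compares mutant-supporting vs
  reference-supporting read-end distances by a one-sided rank-sum test
  (alternative: mutant closer to ends); the variant fails at p < 0.1. The
  5 bp figure survives as a reported diagnostic
  (`end_proximal_fraction`), not a hard cutoff.

Both members of a < 10 bp pair are rejected under criterion IV; positions
are 1-based inclusive throughout.

## CCF estimation and clone clustering

For a mutation at VAF *f* in a tumor of purity ρ with allele-specific copy
number (M, m), the CCF at multiplicity *k* is
`f·(ρ·(M+m) + (1−ρ)·2)/(ρ·k)`. The multiplicity is chosen from 1..M as the
value whose implied CCF is closest to [0, 1] (preferring CCF ≤ 1, largest k
on ties); the result is clipped to [0, 1]. When purity is unavailable it
falls back to 2 × the 95th VAF percentile (capped at 1, diploid
assumption) and the patient is flagged; missing copy number defaults to
(1, 1).

Clustering is a deterministic stand-in for MCMC subclonal reconstruction:
a one-dimensional mixture over CCF, binomial in alt/depth with each
mutation's success probability a known linear map of the clone CCF when
read counts are present, Gaussian on the point estimates otherwise. The
number of clones (1..6 by default) is selected by BIC with ties broken
toward fewer clones; initialisation is by CCF quantiles, so results are
reproducible for a fixed seed. Clone CCF is the median member CCF (robust
to multiplicity mis-calls); clusters are numbered 1..K by descending CCF.
Silent and non-coding mutations inform the clustering but are excluded
from the editing-score tallies. Externally computed assignments can be
imported via `accept_precomputed_clusters`, which applies the same
conventions. The downstream score depends only on the partition and the
clone CCFs, which is why a lighter deterministic model is an acceptable
substitute for full posterior sampling here.

The clusterer is exposed as a scikit-learn-style estimator
(`CCFClusterer`: `fit`/`predict`, `get_params`, fitted attributes
`n_clusters_`, `cluster_ccfs_`, `labels_`), so it composes with sklearn
tooling.

## Scoring choices

* *Neoantigen counting unit.* `load_i` defaults to mutations bearing ≥ 1
  predicted HLA-I binder, which keeps ioTNL ≤ TNL and comparable to
  mutation-level TNL; `count_unit="peptide"` counts predicted
  peptide–allele binders instead, under which clone scores can exceed 1
  (as seen in pan-cancer clone-score landscapes that centre near 1).
  Both units are supported because "number of neoantigens" is ambiguous
  between them.
* *Binder definition.* A peptide–allele pair is a binder at %rank ≤ 2.0 or
  affinity ≤ 500 nM (standard NetMHCpan conventions; the predictor's
  output is consumed, not reproduced). An optional `expressed` column can
  mask binders; no expression model is built.
* *Staging tie rule.* A clone exactly at the cutoff is elimination —
  escape is the strictly-high class.
* *Default cutoff.* 1.0 when no response labels are available to optimise
  it; with labels, the cutoff is grid-searched over 0.5..1.5 in steps of
  0.1, maximising the ROC AUC of the recomputed ioTNL against ORR or DCB
  (AUC ties go to the smaller cutoff).
* *Degenerate clones.* A clone with no non-silent mutations scores 0 and
  can contribute nothing.
* *Reporting transform.* log10(ioTNL + 0.01), so zero scores stay finite;
  the raw score is always emitted too.
* A reference-set ("expected vs observed") editing-score variant is
  deliberately not implemented; the reference-free ratio is the model.

## Cohort statistics

Fisher's exact test uses the minimum-likelihood two-sided definition
(scipy's), which is the definition required to reproduce standard printed
two-sided values. Mann–Whitney is exact for combined n ≤ 20 without ties,
tie-corrected asymptotic otherwise. ROC AUC is the all-pairs probability
P(score⁺ > score⁻) + ½ P(tie) computed by ranks; the Youden cutoff scans
midpoints of sorted unique scores plus ∓∞ sentinels and breaks ties toward
the smallest cutoff. Survival uses lifelines: Kaplan–Meier with the
conventional S(t) ≤ 0.5 median rule (never reached → `None`), the
unweighted Mantel–Haenszel log-rank test, and univariate Cox regression
with Efron tie handling and Wald CIs; separation is flagged rather than
raised. Both Pearson and Spearman correlation are provided and the caller
chooses. Response-rate tests drop NE patients; survival keeps every
patient with a time (the metadata records both counts). All tests are
two-tailed at α = 0.05 with no multiplicity correction.

## Synthetic data: what it emulates, and what it does not

The generators are first-class, tested code and define the conditions the
test-suite checks.

* *Read fixtures.* Clean candidates are constructed to pass all eight
  criteria (depth 80–150, VAF 0.15–0.45, MAPQ 50–60, BQ 30–40, mutant
  reads away from ends, normal 0 alt reads, ≥ 800 bp spacing); planted
  violators are guaranteed by construction to fail their criterion
  (e.g. depth ≤ 9 for coverage violators). A planted violation can entail
  others (two supporting reads can never reach signed-rank significance),
  so per-criterion tallies are lower-bounded, not pinned, by planted
  counts.
* *Patients.* Clone CCFs start at 1.0 and descend with ≥ 0.2 separation;
  2–4 clones of 15–30 mutations (20% silent); sequencing depth 200;
  purity uniform on 0.5–0.9; diploid loci at multiplicity 1 with
  alt ~ Binomial(depth, ρ·CCF/2) — the same observation model the
  inference inverts. Escape clones are planted with a 0.9 neoantigenic
  fraction and elimination clones with 0.3 (the direction is
  configurable), so any staging cutoff between the fractions — 0.6 is the
  config default — recovers the planted stages; truth ioTNL is computed
  by definition from the planted labels.
* *Cohorts.* Response ~ Bernoulli(logistic(−1 + 2·log10(ioTNL + 0.01)))
  (ORR in the 30–50% range typical of checkpoint-inhibitor cohorts); DCB
  agrees with response with probability 0.85; survival is exponential
  with response-group medians 161 vs 61 days (the scale of PFS contrasts
  reported in anti-PD-(L)1 NSCLC) and 20% independent censoring.

Not emulated: sequence-level reads, mutational signatures, clonal
evolution over time, copy-number heterogeneity within a patient (patients
are simulated diploid; non-diploid inversion is exercised by unit tests,
not by the generator), HLA genotype structure, or any correlation between
neoantigen yield and mutation type. Passing tests therefore demonstrate
correctness of the inference and statistics under a faithful but idealised
observation model — not performance on real sequencing artefacts, which
the filter stage can only partially represent.

## Numerical and testing notes

Problem sizes in the test suite (50 seeded tumors of ~60–90 mutations at
depth 200 for recovery; 200 patients for cutoff recovery; n = 500 for Cox
recovery; 1000 replicates for type-I calibration) were chosen as the
smallest sizes at which the checked properties are stable, keeping the
default suite fast. EM convergence is 1e-6 on mean log-likelihood with a
200-iteration cap; component probabilities are clipped to [1e-9, 1−1e-9];
BIC uses 2K−1 free parameters for K components. Determinism: all
randomness flows through `numpy.random.default_rng(seed)`; pipeline reruns
with the same config are byte-identical.

## Known limitations

* The clusterer is a point-estimate stand-in: it reports no uncertainty on
  clone CCFs and has no strict analogue of copy-number prior choices in
  Dirichlet-process tools; heavily aneuploid genomes will stress the
  per-mutation linear-VAF approximation.
* The editing score is undefended for very small clones (a 2-mutation
  clone can only score 0, 0.5 or 1); no shrinkage is applied.
* Expression filtering is a pass-through mask, not a model.
* The cutoff grid search inherits ROC discreteness in small cohorts;
  reported AUC ties are resolved by convention, not evidence.
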