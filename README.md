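# iotnl

Immunoediting-optimized tumor neoantigen load: a biomarker pipeline for
predicting response and prognosis under immune-checkpoint therapy.

Raw neoantigen counts (TNL) and mutation burden (TMB) treat every
neoantigen as equally immunogenic. But a tumor is a mixture of clones, and
a clone that has already undergone immunoediting — whose neoantigens are
tolerised — no longer drives immune elimination. `iotnl` scores each clone's
immunoediting status and restricts the neoantigen load to clones still
under elimination, weighting each by its cellular prevalence:

```
editing_score_i = n_neoantigen_i / n_nonsilent_i
stage_i         = escape  if  editing_score_i > cutoff  else  elimination

ioTNL = Σ_{i ∈ elimination clones}  load_i · CCF_i
```

where `load_i` is the neoantigen load of clone *i* and `CCF_i` its cancer
cell fraction. The package covers the full path from somatic calls to
cohort-level biomarker evaluation, for bioinformaticians analysing
tumor–normal sequencing of immunotherapy cohorts:

* **`iotnl.variants`** — high-confidence somatic SNV/InDel filtering from
  read-level evidence (depth, VAF, support, spacing, mapping/base-quality
  rank tests, read-end position, tumor-vs-normal Fisher).
* **`iotnl.clonal`** — CCF estimation from VAF, purity and allele-specific
  copy number; clone clustering via a deterministic, BIC-selected
  binomial/Gaussian mixture (`CCFClusterer`, a scikit-learn-style
  estimator), plus an import path for external subclonal reconstructions.
* **`iotnl.scoring`** — immune editing score, clone staging, ioTNL, TNL,
  TMB.
* **`iotnl.stats`** — ROC/AUC, Youden dichotomization, editing-cutoff grid
  search, Fisher exact, Mann–Whitney, Kaplan–Meier/log-rank, Cox hazard
  ratios, correlation.
* **`iotnl.simulate`** — synthetic read fixtures, clonal tumors and
  cohorts with known ground truth.
* **`iotnl.io` / `iotnl.cli`** — MAF-like TSV / VCF / segment / epitope /
  clinical table readers-writers and the `iotnl` command-line tool
  (`filter`, `cluster`, `score`, `cohort`, `simulate`, `run`).

## Worked example

The illustrative three-clone tumor: clones 1 and 2 are immune-eliminated
(one neoantigen each at clone CCFs 1.0 and 0.1); clone 3 is immunoedited
(three predicted binders on two mutations, CCF 0.05).

```python
>>> from iotnl import toy_three_clone_tumor, compute_iotnl
>>> scores = compute_iotnl(toy_three_clone_tumor(), cutoff=1.0, count_unit="peptide")
>>> for c in scores.per_clone: print(c)
{'cluster_id': 1, 'n_nonsilent': 2, 'n_neoantigen': 1, 'load': 1, 'ccf': 1.0, 'editing_score': 0.5, 'stage': 'elimination'}
{'cluster_id': 2, 'n_nonsilent': 2, 'n_neoantigen': 1, 'load': 1, 'ccf': 0.1, 'editing_score': 0.5, 'stage': 'elimination'}
{'cluster_id': 3, 'n_nonsilent': 2, 'n_neoantigen': 2, 'load': 3, 'ccf': 0.05, 'editing_score': 1.5, 'stage': 'escape'}
>>> scores.tnl, scores.iotnl
(5.0, 1.1)
```

The tumor carries five neoantigens (TNL = 5), but the three on the escape
clone are discarded and the rest are CCF-weighted, giving
ioTNL = 1·1.0 + 1·0.1 = 1.1.

On a simulated 80-patient cohort whose response is generated from a
logistic link on log10 ioTNL:

```python
>>> from iotnl import SimulationConfig, simulate_cohort, evaluate_dichotomy
>>> cohort, _ = simulate_cohort(SimulationConfig(n_patients=80), seed=7)
>>> res = evaluate_dichotomy(cohort, time_col="pfs_days", event_col="pfs_event")
>>> round(res.auc, 3), res.n_high, res.n_low
(0.794, 48, 32)
>>> round(res.rate_high, 3), round(res.rate_low, 3), res.fisher_p
(0.75, 0.188, 8.857219071758096e-07)
>>> round(res.median_high, 1), round(res.median_low, 1), round(res.logrank_p, 5)
(149.0, 44.7, 0.00027)
>>> round(res.hazard_ratio, 2)
2.66
```

Patients are split at the Youden-optimal ioTNL cutoff: the score
discriminates responders (AUC 0.79), the high-ioTNL group responds at 75%
vs 19% (Fisher p ≈ 9e-7), survives a median 149 vs 45 days, and the
low-score group progresses 2.7× faster (Cox HR on the low-vs-high
indicator).

Command-line equivalent for file-based inputs:

```sh
iotnl run --mutations muts.tsv --epitopes binders.tsv --clinical clin.tsv \
          --optimize-cutoff --out results/
```

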