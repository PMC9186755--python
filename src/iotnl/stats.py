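"""Cohort-level biomarker statistics.

Everything needed to evaluate a continuous biomarker (ioTNL, TNL, TMB)
against immunotherapy outcomes on a cohort table: ROC/AUC, Youden-index
dichotomization, the editing-score cutoff grid search, Fisher's exact test,
the Mann-Whitney U test, Kaplan-Meier curves with the log-rank test, Cox
proportional-hazards ratios, and Pearson/Spearman correlation.

All tests are two-tailed; no multiple-testing correction is applied.  The
two-sided Fisher p-value is the minimum-likelihood definition (sum of
hypergeometric probabilities of all tables with the observed margins no
more probable than the observed one).  Response-rate tests drop
not-evaluable (NE) patients; survival analyses keep every patient with a
recorded time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "roc_auc",
    "youden_cutoff",
    "optimize_editing_cutoff",
    "fisher_exact_two_sided",
    "mann_whitney_u",
    "km_logrank",
    "cox_hr",
    "correlation",
    "DichotomyResult",
    "evaluate_dichotomy",
    "RESPONSE_CATEGORIES",
    "orr_label",
]

RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD", "NE")
_OBJECTIVE = frozenset({"CR", "PR"})


def orr_label(response: str) -> str:
    """Objective response (ORR = CR/PR) vs no objective response (NOR = SD/PD); NE stays NE."""
    if response in _OBJECTIVE:
        return "ORR"
    if response in ("SD", "PD"):
        return "NOR"
    return "NE"


def _check_two_classes(labels: np.ndarray) -> np.ndarray:
    pos = np.asarray(labels, dtype=bool)
    if pos.all() or (~pos).all():
        raise ValueError("both outcome classes must be present")
    return pos


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Area under the ROC curve: P(score_pos > score_neg) + 1/2 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    pos = _check_two_classes(labels)
    # rank formulation of the all-pairs probability (Mann-Whitney statistic)
    ranks = stats.rankdata(scores)
    n_pos = int(pos.sum())
    n_neg = pos.size - n_pos
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def youden_cutoff(
    scores: Sequence[float], labels: Sequence[bool]
) -> tuple[float, float, float]:
    """Dichotomization threshold maximising Youden's J = sensitivity + specificity - 1.

    Candidate thresholds are the midpoints of consecutive sorted unique
    scores plus -inf/+inf sentinels; a patient is called high/positive when
    score > threshold.  Ties in J go to the smallest threshold.  Returns
    (cutoff, sensitivity, specificity) at the chosen threshold.
    """
    scores = np.asarray(scores, dtype=float)
    pos = _check_two_classes(labels)
    uniq = np.unique(scores)
    candidates = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]))
    if uniq.size == 1:
        warnings.warn("all scores identical; Youden cutoff is degenerate", stacklevel=2)
    n_pos = int(pos.sum())
    n_neg = pos.size - n_pos
    best = None
    for cut in candidates:
        pred_hi = scores > cut
        sens = float((pred_hi & pos).sum() / n_pos)
        spec = float((~pred_hi & ~pos).sum() / n_neg)
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, cut, sens, spec)
    _, cut, sens, spec = best
    return float(cut), sens, spec


def fisher_exact_two_sided(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table (minimum-likelihood definition).

    A table with an all-zero row or column carries no information; p = 1 is
    returned with a warning.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("zero margin in 2x2 table; p set to 1", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null distribution for combined n <= 20 without ties, tie-corrected
    normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def optimize_editing_cutoff(
    cohort_builder: Callable[[float], pd.DataFrame],
    grid_start: float = 0.5,
    grid_stop: float = 1.5,
    grid_step: float = 0.1,
    label: Literal["ORR", "DCB"] = "ORR",
) -> tuple[float, dict[float, float]]:
    """Grid-search the immune-editing cutoff maximising the ioTNL ROC AUC.

    ``cohort_builder(cutoff)`` must return a cohort table with an ``iotnl``
    column and the outcome column (``orr_label`` in {ORR, NOR} or
    ``dcb_label`` in {DCB, NDB}) with every patient's ioTNL recomputed at
    that clone-staging cutoff.  The default grid is 0.5 to 1.5 in steps of
    0.1; AUC ties go to the smaller cutoff.
    """
    if grid_step <= 0 or grid_stop < grid_start:
        raise ValueError("grid must satisfy start <= stop and step > 0")
    n_steps = int(round((grid_stop - grid_start) / grid_step))
    grid = [round(grid_start + i * grid_step, 10) for i in range(n_steps + 1)]
    col = {"ORR": "orr_label", "DCB": "dcb_label"}[label]
    pos_value = {"ORR": "ORR", "DCB": "DCB"}[label]
    auc_per_cutoff: dict[float, float] = {}
    best_cutoff, best_auc = None, -np.inf
    for cut in grid:
        table = cohort_builder(cut)
        evaluable = table[table[col] != "NE"]
        labels = (evaluable[col] == pos_value).to_numpy()
        auc = roc_auc(evaluable["iotnl"].to_numpy(), labels)
        auc_per_cutoff[cut] = auc
        if auc > best_auc + 1e-12:
            best_cutoff, best_auc = cut, auc
    return best_cutoff, auc_per_cutoff


def km_logrank(
    groups: Sequence[tuple[Sequence[float], Sequence[int]]],
    group_names: Sequence[str] | None = None,
) -> dict:
    """Kaplan-Meier curves, per-group median survival and the log-rank p-value.

    ``groups`` is a list of (times, event flags) pairs, one per group; the
    log-rank test is the unweighted (Mantel-Haenszel) form.  A group median
    is the first time the survival curve drops to 0.5 or below; if the curve
    never does, the median is reported as None (not reached).
    """
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    names = list(group_names) if group_names is not None else [str(i) for i in range(len(groups))]
    total_events = sum(int(np.asarray(e).sum()) for _, e in groups)
    medians: dict[str, float | None] = {}
    curves: dict[str, pd.DataFrame] = {}
    for name, (t, e) in zip(names, groups):
        kmf = KaplanMeierFitter()
        kmf.fit(np.asarray(t, dtype=float), np.asarray(e, dtype=int), label=name)
        med = kmf.median_survival_time_
        medians[name] = None if np.isinf(med) else float(med)
        curves[name] = kmf.survival_function_.reset_index().rename(
            columns={"timeline": "time", name: "survival"}
        )
    if total_events == 0:
        warnings.warn("no events in any group; log-rank p undefined", stacklevel=2)
        return {"medians": medians, "logrank_p": None, "curves": curves, "no_events": True}
    all_t = np.concatenate([np.asarray(t, dtype=float) for t, _ in groups])
    all_e = np.concatenate([np.asarray(e, dtype=int) for _, e in groups])
    all_g = np.concatenate([np.repeat(n, len(t)) for n, (t, _) in zip(names, groups)])
    res = multivariate_logrank_test(all_t, all_g, all_e)
    return {
        "medians": medians,
        "logrank_p": float(res.p_value),
        "chi2": float(res.test_statistic),
        "curves": curves,
        "no_events": False,
    }


def cox_hr(
    covariate: Sequence[float],
    times: Sequence[float],
    events: Sequence[int],
) -> dict:
    """Univariate Cox proportional-hazards fit (Efron ties): HR, Wald 95% CI, p.

    Monotone-likelihood separation (e.g. all events in one group) is flagged
    rather than raised; the CI is effectively unbounded there.
    """
    cov = np.asarray(covariate, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if e.sum() < 1:
        raise ValueError("at least one event is required")
    if np.unique(cov).size < 2:
        raise ValueError("covariate is constant")
    df = pd.DataFrame({"x": cov, "time": t, "event": e})
    cph = CoxPHFitter()
    flagged = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except ConvergenceError as err:
            return {"hr": None, "ci95": (None, None), "p": None,
                    "flagged": True, "reason": str(err)}
        flagged = any("convergence" in str(w.message).lower() for w in caught)
    coef = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    lo, hi = np.exp(coef - 1.959964 * se), np.exp(coef + 1.959964 * se)
    return {
        "hr": float(np.exp(coef)),
        "ci95": (float(lo), float(hi)),
        "p": float(cph.summary.loc["x", "p"]),
        "flagged": flagged,
    }


def correlation(
    x: Sequence[float],
    y: Sequence[float],
    method: Literal["pearson", "spearman"] = "pearson",
) -> tuple[float, float]:
    """Pearson or Spearman correlation with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("correlation undefined for a constant vector")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


@dataclass
class DichotomyResult:
    """Outcome comparison of biomarker-high vs -low groups at a cutoff."""

    cutoff: float
    n_high: int
    n_low: int
    rate_high: float
    rate_low: float
    fisher_p: float
    auc: float
    sensitivity: float
    specificity: float
    median_high: float | None = None
    median_low: float | None = None
    logrank_p: float | None = None
    hazard_ratio: float | None = None
    hr_ci95: tuple[float | None, float | None] = (None, None)
    hr_p: float | None = None
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["hr_ci95"] = list(self.hr_ci95)
        return d


def evaluate_dichotomy(
    cohort: pd.DataFrame,
    score_col: str = "iotnl",
    label_col: str = "orr_label",
    positive: str = "ORR",
    time_col: str | None = None,
    event_col: str | None = None,
    cutoff: float | None = None,
) -> DichotomyResult:
    """Dichotomize a biomarker at the Youden cutoff and run the cohort comparisons.

    Response statistics (AUC, Youden cutoff, Fisher 2x2 on response rates)
    use the NE-excluded evaluable set; survival statistics (KM medians,
    log-rank, Cox HR on the high/low indicator) use every patient with a
    recorded time.  An explicit ``cutoff`` overrides the Youden choice.
    """
    evaluable = cohort[cohort[label_col] != "NE"]
    labels = (evaluable[label_col] == positive).to_numpy()
    scores = evaluable[score_col].to_numpy(dtype=float)
    auc = roc_auc(scores, labels)
    if cutoff is None:
        cutoff, sens, spec = youden_cutoff(scores, labels)
    else:
        pred_hi = scores > cutoff
        sens = float((pred_hi & labels).sum() / max(labels.sum(), 1))
        spec = float((~pred_hi & ~labels).sum() / max((~labels).sum(), 1))
    hi = scores > cutoff
    table = [
        [int((hi & labels).sum()), int((hi & ~labels).sum())],
        [int((~hi & labels).sum()), int((~hi & ~labels).sum())],
    ]
    res = DichotomyResult(
        cutoff=float(cutoff),
        n_high=int(hi.sum()),
        n_low=int((~hi).sum()),
        rate_high=float((hi & labels).sum() / hi.sum()) if hi.any() else float("nan"),
        rate_low=float(((~hi) & labels).sum() / (~hi).sum()) if (~hi).any() else float("nan"),
        fisher_p=fisher_exact_two_sided(table),
        auc=auc,
        sensitivity=sens,
        specificity=spec,
        metadata={
            "n_enrolled": int(len(cohort)),
            "n_evaluable": int(len(evaluable)),
            "ne_excluded_from_response": int(len(cohort) - len(evaluable)),
            "positive_label": positive,
        },
    )
    if time_col is not None and event_col is not None:
        surv = cohort.dropna(subset=[time_col])
        s_scores = surv[score_col].to_numpy(dtype=float)
        s_hi = s_scores > cutoff
        if s_hi.any() and (~s_hi).any():
            km = km_logrank(
                [
                    (surv.loc[s_hi, time_col], surv.loc[s_hi, event_col]),
                    (surv.loc[~s_hi, time_col], surv.loc[~s_hi, event_col]),
                ],
                group_names=["high", "low"],
            )
            res.median_high = km["medians"]["high"]
            res.median_low = km["medians"]["low"]
            res.logrank_p = km["logrank_p"]
            # HR of the low-vs-high indicator: >1 means low-score patients
            # progress/die faster, matching a protective high biomarker
            cox = cox_hr((~s_hi).astype(float), surv[time_col], surv[event_col])
            res.hazard_ratio = cox["hr"]
            res.hr_ci95 = cox["ci95"]
            res.hr_p = cox["p"]
    return res
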