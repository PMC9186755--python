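"""Synthetic tumor-sequencing data with known ground truth.

Three generators cover every input the pipeline consumes:

* :func:`simulate_read_fixture` — candidate SNVs with read-level evidence
  and planted filter-criterion violations, for exercising the variant
  filter.
* :func:`simulate_patient` — a clonal tumor: clone CCFs with a minimum
  separation, per-clone mutation counts, binomial read counts at the VAF
  implied by purity and (diploid) copy number, and planted immunoediting
  structure (escape clones carry a high neoantigenic fraction, elimination
  clones a low one).
* :func:`simulate_cohort` — many patients with response drawn from a
  logistic link on log10(ioTNL + 0.01), durable-benefit labels correlated
  with response, and exponential survival with response-group-specific
  hazards plus independent censoring.

All generators are deterministic under a fixed seed.  The observation model
for read counts is alt ~ Binomial(depth, VAF) with
VAF = purity * CCF * m / (purity * CN_t + (1 - purity) * 2), the same
relation the clonal-inference module inverts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .clonal import CloneCluster, SomaticMutation, accept_precomputed_clusters, expected_vaf
from .scoring import LOG10_OFFSET
from .variants import CandidateVariant

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "simulate_read_fixture",
    "simulate_patient",
    "simulate_cohort",
    "simulate_planted_cutoff_cohort",
    "toy_three_clone_tumor",
]


@dataclass
class SimulationConfig:
    """Generative settings for patients and cohorts.

    Clone CCFs start at 1.0 (truncal clone) and descend with at least
    ``min_ccf_separation`` between consecutive clones.  Escape clones are
    planted with a high neoantigenic fraction and elimination clones with a
    low one, so a staging cutoff between the two fractions recovers the
    planted stages; ``editing_cutoff`` is that cutoff.  Survival medians
    default to 161 vs 61 days for responders vs non-responders, the scale
    of progression-free survival differences seen in checkpoint-inhibitor
    NSCLC cohorts.
    """

    n_patients: int = 50
    clones_min: int = 2
    clones_max: int = 4
    min_ccf_separation: float = 0.2
    min_ccf: float = 0.05
    mutations_per_clone_min: int = 15
    mutations_per_clone_max: int = 30
    neo_fraction_elimination: float = 0.3
    neo_fraction_escape: float = 0.9
    escape_clone_prob: float = 0.35
    editing_cutoff: float = 0.6
    silent_fraction: float = 0.2
    depth: int = 200
    purity_min: float = 0.5
    purity_max: float = 0.9
    region_mb: float = 30.0
    response_intercept: float = -1.0
    response_slope: float = 2.0
    dcb_agreement: float = 0.85
    median_surv_responder_days: float = 161.0
    median_surv_nonresponder_days: float = 61.0
    censoring_rate: float = 0.2

    def __post_init__(self) -> None:
        for name in ("neo_fraction_elimination", "neo_fraction_escape", "escape_clone_prob",
                     "silent_fraction", "censoring_rate", "dcb_agreement"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0.0 < self.purity_min <= self.purity_max <= 1.0:
            raise ValueError("purity range must satisfy 0 < min <= max <= 1")


@dataclass
class TruthRecord:
    """Ground truth for one simulated patient."""

    patient_id: str
    purity: float
    clone_ccfs: list[float]
    clone_stages: list[str]
    clone_n_nonsilent: list[int]
    clone_loads: list[int]
    clone_editing_scores: list[float]
    mutation_labels: dict[str, int] = field(default_factory=dict)
    tnl: float = 0.0
    iotnl: float = 0.0
    tmb: float = 0.0
    response_prob: float | None = None


# ---------------------------------------------------------------------------
# read-level fixtures for the variant filter
# ---------------------------------------------------------------------------

_PLANTABLE = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")


def _clean_variant(rng: np.random.Generator, chrom: str, pos: int) -> CandidateVariant:
    """A candidate that satisfies every SNV criterion by construction."""
    depth = int(rng.integers(80, 150))
    vaf = float(rng.uniform(0.15, 0.45))
    alt = int(np.clip(rng.binomial(depth, vaf), 8, depth))
    return CandidateVariant(
        chrom=chrom, pos=pos, ref="C", alt="T", variant_class="SNV",
        effect="missense",
        tumor_depth=depth, tumor_alt_count=alt,
        normal_depth=int(rng.integers(60, 120)), normal_alt_count=0,
        mutant_mapqs=list(rng.integers(50, 61, size=alt).astype(float)),
        mutant_baseqs=list(rng.integers(30, 41, size=alt).astype(float)),
        mutant_end_distances=list(rng.uniform(30, 70, size=alt)),
        ref_end_distances=list(rng.uniform(5, 40, size=depth - alt)),
    )


def _plant(rng: np.random.Generator, v: CandidateVariant, criterion: str) -> CandidateVariant:
    """Mutate a clean candidate so it is guaranteed to fail one criterion."""
    if criterion == "I":
        alt = 6
        v.tumor_depth, v.tumor_alt_count = 9, alt
        v.normal_depth, v.normal_alt_count = 9, 0
        v.mutant_mapqs = v.mutant_mapqs[:alt]
        v.mutant_baseqs = v.mutant_baseqs[:alt]
        v.mutant_end_distances = v.mutant_end_distances[:alt]
        v.ref_end_distances = v.ref_end_distances[: v.tumor_depth - alt]
    elif criterion == "II":
        # normal contamination: normal VAF >= 2%
        v.normal_depth, v.normal_alt_count = 100, int(rng.integers(3, 8))
    elif criterion == "III":
        alt = 2
        v.tumor_depth, v.tumor_alt_count = 30, alt
        v.mutant_mapqs = v.mutant_mapqs[:alt]
        v.mutant_baseqs = v.mutant_baseqs[:alt]
        v.mutant_end_distances = v.mutant_end_distances[:alt]
        v.ref_end_distances = v.ref_end_distances[: v.tumor_depth - alt]
    elif criterion == "V":
        v.mutant_mapqs = list(rng.integers(18, 29, size=v.tumor_alt_count).astype(float))
    elif criterion == "VI":
        v.mutant_baseqs = list(rng.integers(8, 19, size=v.tumor_alt_count).astype(float))
    elif criterion == "VII":
        v.mutant_end_distances = list(rng.uniform(0, 4, size=v.tumor_alt_count))
        v.ref_end_distances = list(rng.uniform(30, 70, size=max(len(v.ref_end_distances), 20)))
    elif criterion == "VIII":
        # tumor and normal allele fractions too similar to call somatic
        v.tumor_depth, v.tumor_alt_count = 120, 6
        v.normal_depth, v.normal_alt_count = 10, 0
        v.mutant_mapqs = v.mutant_mapqs[:6]
        v.mutant_baseqs = v.mutant_baseqs[:6]
        v.mutant_end_distances = v.mutant_end_distances[:6]
    else:  # pragma: no cover
        raise ValueError(f"cannot plant criterion {criterion}")
    return v


def simulate_read_fixture(
    n_variants: int,
    violation_mix: Mapping[str, float] | None = None,
    seed: int = 0,
) -> tuple[list[CandidateVariant], list[set[str]]]:
    """Candidate SNVs with planted criterion violations.

    ``violation_mix`` maps criterion labels (I..VIII) to the fraction of
    variants planted to violate that criterion; the fractions must sum to
    at most 1 and the remainder of the variants pass every criterion by
    construction.  Criterion IV is planted as an adjacent pair (both
    members fail), consuming two variants per planted event.

    Returns the candidates and, aligned with them, the set of criteria each
    was planted to violate (empty set = clean).  A planted variant can in
    addition fail criteria that are physically entailed (e.g. two
    supporting reads can never reach base-quality significance), so
    per-criterion rejection tallies are lower-bounded, not pinned, by the
    planted counts.
    """
    mix = dict(violation_mix or {})
    unknown = set(mix) - set(_PLANTABLE)
    if unknown:
        raise ValueError(f"unknown criteria in violation_mix: {sorted(unknown)}")
    if sum(mix.values()) > 1.0 + 1e-9:
        raise ValueError("violation_mix fractions must sum to <= 1")
    rng = np.random.default_rng(seed)
    plan: list[str] = []
    for crit in _PLANTABLE:
        plan.extend([crit] * int(round(mix.get(crit, 0.0) * n_variants)))
    plan = plan[:n_variants]
    plan.extend(["clean"] * (n_variants - len(plan)))
    rng.shuffle(plan)

    variants: list[CandidateVariant] = []
    truth: list[set[str]] = []
    pos = 10_000
    for crit in plan:
        pos += int(rng.integers(800, 1500))  # always > 10 bp from the previous call
        v = _clean_variant(rng, "1", pos)
        if crit == "clean":
            variants.append(v)
            truth.append(set())
        elif crit == "IV":
            v2 = _clean_variant(rng, "1", pos + int(rng.integers(1, 10)))
            variants.extend([v, v2])
            truth.extend([{"IV"}, {"IV"}])
        else:
            variants.append(_plant(rng, v, crit))
            truth.append({crit})
    return variants, truth


# ---------------------------------------------------------------------------
# clonal tumors
# ---------------------------------------------------------------------------


def _sample_clone_structure(rng: np.random.Generator, config: SimulationConfig) -> dict:
    """Clone-level truth: CCFs, stages, mutation tallies and neoantigen loads."""
    n_clones = int(rng.integers(config.clones_min, config.clones_max + 1))
    ccfs = [1.0]
    for _ in range(n_clones - 1):
        hi = ccfs[-1] - config.min_ccf_separation
        if hi <= config.min_ccf:
            break
        ccfs.append(float(rng.uniform(config.min_ccf, hi)))
    n_clones = len(ccfs)
    stages, n_nonsilent, n_silent, loads = [], [], [], []
    for _ in range(n_clones):
        stage = "escape" if rng.random() < config.escape_clone_prob else "elimination"
        n_mut = int(rng.integers(config.mutations_per_clone_min, config.mutations_per_clone_max + 1))
        n_sil = int(round(config.silent_fraction * n_mut))
        n_ns = n_mut - n_sil
        frac = config.neo_fraction_escape if stage == "escape" else config.neo_fraction_elimination
        stages.append(stage)
        n_nonsilent.append(n_ns)
        n_silent.append(n_sil)
        loads.append(int(round(frac * n_ns)))
    return {
        "ccfs": ccfs,
        "stages": stages,
        "n_nonsilent": n_nonsilent,
        "n_silent": n_silent,
        "loads": loads,
    }


def _truth_from_structure(
    patient_id: str, purity: float, struct: dict, config: SimulationConfig
) -> TruthRecord:
    scores = [
        (load / n_ns) if n_ns else 0.0
        for load, n_ns in zip(struct["loads"], struct["n_nonsilent"])
    ]
    iotnl = sum(
        load * ccf
        for load, ccf, stage in zip(struct["loads"], struct["ccfs"], struct["stages"])
        if stage == "elimination"
    )
    return TruthRecord(
        patient_id=patient_id,
        purity=purity,
        clone_ccfs=list(struct["ccfs"]),
        clone_stages=list(struct["stages"]),
        clone_n_nonsilent=list(struct["n_nonsilent"]),
        clone_loads=list(struct["loads"]),
        clone_editing_scores=scores,
        tnl=float(sum(struct["loads"])),
        iotnl=float(iotnl),
        tmb=sum(struct["n_nonsilent"]) / config.region_mb,
    )


def simulate_patient(
    config: SimulationConfig,
    seed: int = 0,
    patient_id: str = "P1",
) -> tuple[list[SomaticMutation], TruthRecord]:
    """One clonal tumor: mutation table with read counts plus the truth record.

    Mutations carry VAF, alt/depth counts and diploid copy number; their
    ``ccf`` is left unset for the inference modules to fill.  The truth
    ioTNL is computed by definition from the planted stages and true clone
    CCFs.
    """
    rng = np.random.default_rng(seed)
    purity = float(rng.uniform(config.purity_min, config.purity_max))
    struct = _sample_clone_structure(rng, config)
    truth = _truth_from_structure(patient_id, purity, struct, config)
    mutations: list[SomaticMutation] = []
    idx = 0
    for k, ccf in enumerate(struct["ccfs"]):
        evaf = expected_vaf(ccf, purity)  # diploid, multiplicity 1
        n_ns, n_sil, load = struct["n_nonsilent"][k], struct["n_silent"][k], struct["loads"][k]
        effects = ["missense"] * n_ns + ["silent"] * n_sil
        neo_flags = [True] * load + [False] * (n_ns - load) + [False] * n_sil
        for eff, neo in zip(effects, neo_flags):
            idx += 1
            depth = config.depth
            alt = int(rng.binomial(depth, evaf))
            mut_id = f"{patient_id}:m{idx}"
            mutations.append(
                SomaticMutation(
                    id=mut_id, chrom="1", pos=idx * 10_000, ref="C", alt="T",
                    effect=eff, vaf=alt / depth, alt_count=alt, depth=depth,
                    cn_major=1, cn_minor=1,
                    is_neoantigenic=neo, n_epitopes=1 if neo else 0,
                )
            )
            truth.mutation_labels[mut_id] = k
    return mutations, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


def simulate_cohort(
    config: SimulationConfig,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[TruthRecord]]:
    """A cohort table linking per-patient true scores to response and survival.

    Response is Bernoulli with p = logistic(intercept + slope *
    log10(ioTNL + 0.01)); durable clinical benefit agrees with the response
    label with probability ``dcb_agreement``; progression-free and overall
    survival are exponential with response-group medians from the config,
    censored independently.  Scores in the table are the ground-truth
    values; run the inference pipeline on :func:`simulate_patient` output
    when noisy, estimated scores are wanted.
    """
    rng = np.random.default_rng(seed)
    rows = []
    truths: list[TruthRecord] = []
    for i in range(config.n_patients):
        pid = f"P{i + 1:04d}"
        purity = float(rng.uniform(config.purity_min, config.purity_max))
        struct = _sample_clone_structure(rng, config)
        truth = _truth_from_structure(pid, purity, struct, config)
        p_resp = float(
            expit(config.response_intercept
                  + config.response_slope * math.log10(truth.iotnl + LOG10_OFFSET))
        )
        truth.response_prob = p_resp
        responder = rng.random() < p_resp
        response = ("CR" if rng.random() < 0.2 else "PR") if responder else \
                   ("SD" if rng.random() < 0.5 else "PD")
        agree = rng.random() < config.dcb_agreement
        dcb = ("DCB" if agree else "NDB") if responder else ("NDB" if agree else "DCB")
        med = config.median_surv_responder_days if responder else config.median_surv_nonresponder_days
        surv = {}
        for endpoint, scale in (("pfs", 1.0), ("os", 2.0)):
            t = float(rng.exponential(med * scale / math.log(2)))
            if rng.random() < config.censoring_rate:
                surv[endpoint] = (float(rng.uniform(0, t)), 0)
            else:
                surv[endpoint] = (t, 1)
        rows.append(
            {
                "patient_id": pid,
                "iotnl": truth.iotnl,
                "tnl": truth.tnl,
                "tmb": truth.tmb,
                "log10_iotnl": math.log10(truth.iotnl + LOG10_OFFSET),
                "response": response,
                "orr_label": "ORR" if responder else "NOR",
                "dcb_label": dcb,
                "pfs_days": surv["pfs"][0],
                "pfs_event": surv["pfs"][1],
                "os_days": surv["os"][0],
                "os_event": surv["os"][1],
            }
        )
        truths.append(truth)
    return pd.DataFrame(rows), truths


def simulate_planted_cutoff_cohort(
    n_patients: int = 200,
    planted_cutoff: float = 0.8,
    seed: int = 0,
):
    """A cohort whose response signal lives only in clones scoring at or below a cutoff.

    Each patient gets a truncal clone plus 2-3 subclones with editing
    scores drawn from a discrete menu straddling ``planted_cutoff``
    (loads are exact count ratios on 20 non-silent mutations).  Response is
    Bernoulli on a logistic link of the ioTNL computed *at the planted
    cutoff*, so the ROC AUC of recomputed ioTNL against response peaks at
    that cutoff on the 0.5..1.5 grid.

    Returns ``(cohort_builder, response)`` where ``cohort_builder(cutoff)``
    yields the table :func:`iotnl.stats.optimize_editing_cutoff` expects.
    """
    rng = np.random.default_rng(seed)
    n_ns = 20
    patients: list[list[tuple[float, float, int]]] = []
    for _ in range(n_patients):
        clones = [(s := float(rng.choice([0.25, 0.75])), 1.0, int(round(s * n_ns)))]
        for _ in range(int(rng.integers(2, 4))):
            s = float(rng.choice([0.25, 0.75, 0.85, 0.95]))
            clones.append((s, float(rng.uniform(0.1, 0.9)), int(round(s * n_ns))))
        patients.append(clones)

    def iotnl_at(clones, cut):
        return sum(load * ccf for s, ccf, load in clones if s <= cut + 1e-9)

    signal = np.array([iotnl_at(c, planted_cutoff) for c in patients])
    p_resp = expit(-3.0 + 3.0 * np.log10(signal + LOG10_OFFSET))
    response = rng.random(n_patients) < p_resp

    def cohort_builder(cut: float) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": [f"P{i + 1:04d}" for i in range(n_patients)],
                "iotnl": [iotnl_at(c, cut) for c in patients],
                "orr_label": np.where(response, "ORR", "NOR"),
            }
        )

    return cohort_builder, response


# ---------------------------------------------------------------------------
# the illustrative three-clone tumor
# ---------------------------------------------------------------------------


def toy_three_clone_tumor() -> list[CloneCluster]:
    """The illustrative heterogeneous tumor: three clones, five neoantigens.

    Clones 1 and 2 are immune-eliminated (one neoantigen each, clone CCFs
    1.0 and 0.1); clone 3 is immunoedited (three predicted binders on two
    mutations, CCF 0.05) and scores above the default staging cutoff.
    Scored at the peptide counting unit this gives TNL = 5 and
    ioTNL = 1 * 1.0 + 1 * 0.1 = 1.1.
    """
    def mut(mid, pos, effect, neo, n_epi, vaf, ccf):
        return SomaticMutation(
            id=mid, chrom="1", pos=pos, ref="C", alt="T", effect=effect,
            vaf=vaf, ccf=ccf, is_neoantigenic=neo, n_epitopes=n_epi,
        )

    mutations = [
        mut("m1", 1_000, "missense", True, 1, 0.50, 1.0),
        mut("m2", 2_000, "missense", False, 0, 0.50, 1.0),
        mut("m3", 3_000, "missense", True, 1, 0.05, 0.1),
        mut("m4", 4_000, "missense", False, 0, 0.05, 0.1),
        mut("m5", 5_000, "missense", True, 2, 0.025, 0.05),
        mut("m6", 6_000, "missense", True, 1, 0.025, 0.05),
    ]
    assignments = {"m1": "c1", "m2": "c1", "m3": "c2", "m4": "c2", "m5": "c3", "m6": "c3"}
    return accept_precomputed_clusters(mutations, assignments)
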