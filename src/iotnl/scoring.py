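"""Immune editing score, clone staging and the ioTNL patient score.

Each tumor clone gets an immune editing score — the ratio of its neoantigen
load to its non-silent mutation count.  A clone scoring above a cutoff is
considered immune-*escape* (its neoantigens have been tolerised and no
longer drive elimination); otherwise it is immune-*elimination*.  The
patient-level score restricts the neoantigen load to elimination clones and
weights each clone's load by its cancer cell fraction:

    ioTNL = sum over elimination clones i of load_i * CCF_i

TNL (total neoantigen load) sums load_i over all clones regardless of
stage, and TMB is the non-silent mutation count per megabase of assayed
territory.  The neoantigen-load unit is configurable: ``"mutation"``
(default) counts mutations bearing at least one predicted HLA-I binder, so
ioTNL <= TNL is comparable with mutation-level TNL; ``"peptide"`` counts
predicted peptide-allele binders, under which per-clone scores can exceed 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

from .clonal import CloneCluster, SomaticMutation

__all__ = [
    "PatientScores",
    "immune_editing_score",
    "classify_clone",
    "compute_iotnl",
    "compute_tmb",
    "DEFAULT_EDITING_CUTOFF",
    "LOG10_OFFSET",
]

CountUnit = Literal["mutation", "peptide"]

#: Editing-score cutoff used when no response labels are available to
#: optimise it over the 0.5..1.5 grid; clone scores across cancers centre
#: on a median of about 1.
DEFAULT_EDITING_CUTOFF = 1.0

#: Offset inside the log10 reporting transform so zero scores stay finite.
LOG10_OFFSET = 0.01


@dataclass
class PatientScores:
    """TNL, TMB and ioTNL for one patient with the per-clone breakdown."""

    patient_id: str
    tnl: float
    tmb: float | None
    iotnl: float
    n_elimination: int
    n_escape: int
    per_clone: list[dict] = field(default_factory=list)
    empty: bool = False

    @property
    def log10_iotnl(self) -> float:
        return math.log10(self.iotnl + LOG10_OFFSET)


def _clone_load(clone: CloneCluster, count_unit: CountUnit) -> int:
    if count_unit == "mutation":
        return clone.n_neoantigen
    if count_unit == "peptide":
        return clone.n_epitopes
    raise ValueError(f"unknown count_unit {count_unit!r}")


def immune_editing_score(clone: CloneCluster, count_unit: CountUnit = "mutation") -> float:
    """Ratio of the clone's neoantigen load to its non-silent mutation count.

    A clone with no non-silent mutations is degenerate — it can hold no
    neoantigens — and scores 0 (it contributes nothing downstream).
    """
    if clone.n_nonsilent < 0 or clone.n_neoantigen < 0:
        raise ValueError("clone tallies must be non-negative")
    if clone.n_nonsilent == 0:
        return 0.0
    return _clone_load(clone, count_unit) / clone.n_nonsilent


def classify_clone(score: float, cutoff: float = DEFAULT_EDITING_CUTOFF) -> str:
    """Stage a clone: score above the cutoff is escape, otherwise elimination.

    The boundary (score == cutoff) counts as elimination: escape is the
    strictly-high class.
    """
    if cutoff < 0:
        raise ValueError(f"cutoff must be >= 0, got {cutoff}")
    return "escape" if score > cutoff else "elimination"


def compute_iotnl(
    clones: Sequence[CloneCluster],
    cutoff: float = DEFAULT_EDITING_CUTOFF,
    *,
    patient_id: str = "",
    tmb: float | None = None,
    count_unit: CountUnit = "mutation",
) -> PatientScores:
    """Score a patient's clone set: TNL over all clones, ioTNL over elimination clones.

    Fills each clone's ``editing_score`` and ``stage`` in place and returns
    the aggregated :class:`PatientScores`.  An empty clone list yields zero
    scores with ``empty=True``.
    """
    if not clones:
        return PatientScores(
            patient_id=patient_id, tnl=0.0, tmb=tmb, iotnl=0.0,
            n_elimination=0, n_escape=0, empty=True,
        )
    tnl = 0.0
    iotnl = 0.0
    n_elim = n_esc = 0
    per_clone: list[dict] = []
    for clone in clones:
        score = immune_editing_score(clone, count_unit)
        stage = classify_clone(score, cutoff)
        clone.editing_score = score
        clone.stage = stage
        load = _clone_load(clone, count_unit)
        tnl += load
        if stage == "elimination":
            n_elim += 1
            iotnl += load * clone.ccf
        else:
            n_esc += 1
        per_clone.append(
            {
                "cluster_id": clone.cluster_id,
                "n_nonsilent": clone.n_nonsilent,
                "n_neoantigen": clone.n_neoantigen,
                "load": load,
                "ccf": clone.ccf,
                "editing_score": score,
                "stage": stage,
            }
        )
    return PatientScores(
        patient_id=patient_id,
        tnl=tnl,
        tmb=tmb,
        iotnl=iotnl,
        n_elimination=n_elim,
        n_escape=n_esc,
        per_clone=per_clone,
    )


def compute_tmb(mutations: Sequence[SomaticMutation], region_mb: float) -> float:
    """Tumor mutation burden: non-silent mutations per megabase of assayed region."""
    if region_mb <= 0:
        raise ValueError(f"region_mb must be > 0, got {region_mb}")
    return sum(1 for m in mutations if m.is_non_silent) / region_mb
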