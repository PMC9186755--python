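"""High-confidence somatic variant filtering from read-level evidence.

Candidate SNVs arrive pre-called (tumor/normal read counts plus per-read
mapping qualities, base qualities and read-end distances for the
mutant-supporting reads) and are screened against eight criteria:

I     tumor and normal depth >= 10x
II    tumor VAF >= 5%, normal VAF < 2%
III   >= 3 mutant-supporting reads in the tumor
IV    > 10 bp from the nearest other candidate SNV on the chromosome
V     mutant-read mapping qualities significantly above 30 (p < 0.2)
VI    mutant-read base qualities significantly above 20 (p < 0.05)
VII   mutant reads not enriched near read ends relative to reference
      reads (one-sided rank-sum, fail if p < 0.1)
VIII  tumor vs normal allele counts differ (two-sided Fisher, p < 0.05)

InDels are screened separately: tumor VAF >= 10% and not germline.

The "significantly above a constant" tests (V, VI) are one-sided Wilcoxon
signed-rank tests on (quality - threshold); a two-sample rank-sum test is
undefined against a scalar.  Zero differences are dropped before ranking
(Wilcoxon's handling; Pratt's is available via ``zero_method``).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CandidateVariant",
    "FilterReport",
    "rank_test_vs_threshold",
    "filter_snvs",
    "filter_indels",
    "SNV_CRITERIA",
]

VariantClass = Literal["SNV", "insertion", "deletion"]
Effect = Literal[
    "missense",
    "nonsense",
    "frameshift_indel",
    "inframe_indel",
    "splice",
    "silent",
    "noncoding",
]

NON_SILENT_EFFECTS = frozenset(
    {"missense", "nonsense", "frameshift_indel", "inframe_indel", "splice"}
)

SNV_CRITERIA = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")

#: diagnostic only -- the fraction of mutant reads within this many bp of a
#: read end is reported, but criterion VII itself is the rank-sum comparison
END_PROXIMITY_BP = 5

_MAPQ_THRESHOLD = 30.0
_BASEQ_THRESHOLD = 20.0
_MAPQ_ALPHA = 0.2
_BASEQ_ALPHA = 0.05
_END_ALPHA = 0.1
_FISHER_ALPHA = 0.05
_MIN_DEPTH = 10
_MIN_TUMOR_VAF = 0.05
_MAX_NORMAL_VAF = 0.02
_MIN_ALT_READS = 3
_MIN_SNV_SPACING_BP = 10
_MIN_INDEL_VAF = 0.10


@dataclass
class CandidateVariant:
    """One putative somatic call with the read-level evidence needed to filter it."""

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: VariantClass
    effect: Effect
    tumor_depth: int
    tumor_alt_count: int
    normal_depth: int
    normal_alt_count: int
    mutant_mapqs: list[float] = field(default_factory=list)
    mutant_baseqs: list[float] = field(default_factory=list)
    mutant_end_distances: list[float] = field(default_factory=list)
    ref_end_distances: list[float] = field(default_factory=list)
    germline_flag: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1 (1-based), got {self.pos}")
        for name in ("tumor_depth", "tumor_alt_count", "normal_depth", "normal_alt_count"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.tumor_alt_count > self.tumor_depth:
            raise ValueError(
                f"tumor_alt_count {self.tumor_alt_count} exceeds tumor_depth {self.tumor_depth}"
            )
        if self.normal_alt_count > self.normal_depth:
            raise ValueError(
                f"normal_alt_count {self.normal_alt_count} exceeds normal_depth {self.normal_depth}"
            )
        for name in ("mutant_mapqs", "mutant_baseqs", "mutant_end_distances", "ref_end_distances"):
            if any(q < 0 for q in getattr(self, name)):
                raise ValueError(f"{name} contains negative values")
        if self.variant_class == "SNV" and self.mutant_mapqs and self.mutant_baseqs:
            if not (len(self.mutant_mapqs) == len(self.mutant_baseqs) == self.tumor_alt_count):
                raise ValueError(
                    "mutant_mapqs and mutant_baseqs must each have one entry per "
                    f"mutant-supporting read (tumor_alt_count={self.tumor_alt_count})"
                )

    @property
    def tumor_vaf(self) -> float:
        return self.tumor_alt_count / self.tumor_depth if self.tumor_depth else 0.0

    @property
    def normal_vaf(self) -> float:
        return self.normal_alt_count / self.normal_depth if self.normal_depth else 0.0

    @property
    def end_proximal_fraction(self) -> float:
        """Fraction of mutant-supporting reads with the variant within 5 bp of a read end."""
        if not self.mutant_end_distances:
            return float("nan")
        near = sum(1 for d in self.mutant_end_distances if d <= END_PROXIMITY_BP)
        return near / len(self.mutant_end_distances)


@dataclass
class FilterReport:
    """Tally of how many candidates failed each criterion (a variant may fail several)."""

    n_input: int = 0
    n_passed: int = 0
    rejections: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_passed": self.n_passed,
            "rejections": dict(self.rejections),
        }


class InsufficientEvidenceError(ValueError):
    """Raised when a significance test has no observations to test."""


def rank_test_vs_threshold(
    values: Sequence[float],
    threshold: float,
    alternative: str = "greater",
    zero_method: str = "wilcox",
) -> float:
    """One-sided signed-rank p-value that ``values`` exceed a constant threshold.

    Parameters
    ----------
    values
        Per-read qualities; must be non-empty.
    threshold
        The constant the qualities are compared against.
    alternative
        Only ``"greater"`` is meaningful here (qualities above threshold).
    zero_method
        How zero differences are handled: ``"wilcox"`` drops them (default),
        ``"pratt"`` ranks them then drops.

    Returns
    -------
    float
        The p-value; 1.0 when every difference is zero (no evidence either way).
    """
    if len(values) == 0:
        raise InsufficientEvidenceError("no observations to test against threshold")
    diffs = np.asarray(values, dtype=float) - threshold
    if np.all(diffs == 0):
        return 1.0
    n_nonzero = int(np.count_nonzero(diffs))
    # exact null distribution for small n when it is well defined (no ties among
    # |differences|, no zeros); tie-corrected normal approximation otherwise
    abs_nonzero = np.abs(diffs[diffs != 0])
    exact_ok = (
        n_nonzero <= 25
        and not np.any(diffs == 0)
        and len(np.unique(abs_nonzero)) == len(abs_nonzero)
    )
    method = "exact" if exact_ok else "approx"
    res = stats.wilcoxon(
        diffs, alternative=alternative, zero_method=zero_method, method=method
    )
    return float(res.pvalue)


def _snv_failures(v: CandidateVariant) -> list[str]:
    """Criteria I-III and V-VIII for one variant (IV needs the whole batch)."""
    failed: list[str] = []
    if v.tumor_depth < _MIN_DEPTH or v.normal_depth < _MIN_DEPTH:
        failed.append("I")
    if v.tumor_vaf < _MIN_TUMOR_VAF or v.normal_vaf >= _MAX_NORMAL_VAF:
        failed.append("II")
    if v.tumor_alt_count < _MIN_ALT_READS:
        failed.append("III")
    # V: mutant mapping qualities significantly above 30
    try:
        if rank_test_vs_threshold(v.mutant_mapqs, _MAPQ_THRESHOLD) >= _MAPQ_ALPHA:
            failed.append("V")
    except InsufficientEvidenceError:
        failed.append("V")
        failed.append("insufficient_evidence")
    # VI: mutant base qualities significantly above 20
    try:
        if rank_test_vs_threshold(v.mutant_baseqs, _BASEQ_THRESHOLD) >= _BASEQ_ALPHA:
            failed.append("VI")
    except InsufficientEvidenceError:
        failed.append("VI")
        if "insufficient_evidence" not in failed:
            failed.append("insufficient_evidence")
    # VII: mutant reads not enriched near read ends relative to reference reads;
    # fail when mutant end distances are significantly smaller
    if not v.mutant_end_distances or not v.ref_end_distances:
        failed.append("VII")
        if "insufficient_evidence" not in failed:
            failed.append("insufficient_evidence")
    else:
        p_end = stats.mannwhitneyu(
            v.mutant_end_distances, v.ref_end_distances, alternative="less"
        ).pvalue
        if p_end < _END_ALPHA:
            failed.append("VII")
    # VIII: tumor vs normal allele-count contrast
    table = [
        [v.tumor_alt_count, v.tumor_depth - v.tumor_alt_count],
        [v.normal_alt_count, v.normal_depth - v.normal_alt_count],
    ]
    if stats.fisher_exact(table, alternative="two-sided")[1] >= _FISHER_ALPHA:
        failed.append("VIII")
    return failed


def _proximity_failures(candidates: Sequence[CandidateVariant]) -> set[int]:
    """Indices failing criterion IV: another candidate SNV within 10 bp on the same chromosome."""
    failed: set[int] = set()
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for i, v in enumerate(candidates):
        by_chrom.setdefault(v.chrom, []).append((v.pos, i))
    for pairs in by_chrom.values():
        pairs.sort()
        for (p1, i1), (p2, i2) in zip(pairs, pairs[1:]):
            if p2 - p1 <= _MIN_SNV_SPACING_BP:
                failed.add(i1)
                failed.add(i2)
    return failed


def filter_snvs(
    candidates: Sequence[CandidateVariant],
) -> tuple[list[CandidateVariant], FilterReport]:
    """Apply the eight high-confidence somatic SNV criteria.

    Returns the passing variants (input order preserved) and a
    :class:`FilterReport` tallying every criterion each variant failed.
    """
    for v in candidates:
        if v.variant_class != "SNV":
            raise ValueError(f"filter_snvs expects SNVs, got {v.variant_class} at {v.chrom}:{v.pos}")
    tally: Counter[str] = Counter()
    too_close = _proximity_failures(candidates)
    passed: list[CandidateVariant] = []
    for i, v in enumerate(candidates):
        failed = _snv_failures(v)
        if i in too_close:
            failed.append("IV")
        tally.update(failed)
        if not failed:
            passed.append(v)
    report = FilterReport(
        n_input=len(candidates), n_passed=len(passed), rejections=dict(tally)
    )
    return passed, report


def filter_indels(
    candidates: Sequence[CandidateVariant],
) -> tuple[list[CandidateVariant], FilterReport]:
    """High-confidence somatic InDels: tumor VAF >= 10% and not a germline event."""
    for v in candidates:
        if v.variant_class not in ("insertion", "deletion"):
            raise ValueError(
                f"filter_indels expects insertions/deletions, got {v.variant_class} at {v.chrom}:{v.pos}"
            )
    tally: Counter[str] = Counter()
    passed: list[CandidateVariant] = []
    for v in candidates:
        failed = []
        if v.tumor_vaf < _MIN_INDEL_VAF:
            failed.append("indel_vaf")
        if v.germline_flag:
            failed.append("indel_germline")
        tally.update(failed)
        if not failed:
            passed.append(v)
    report = FilterReport(
        n_input=len(candidates), n_passed=len(passed), rejections=dict(tally)
    )
    return passed, report
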