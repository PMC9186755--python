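"""Cancer cell fraction estimation and clone clustering.

A somatic mutation observed at VAF ``f`` in a tumor of purity ``rho`` with
allele-specific copy number (major, minor) sits on ``m`` copies of the
mutated allele in the tumor cells that carry it.  Its cancer cell fraction
(the fraction of tumor cells carrying it) is

    CCF = f * (rho * CN_t + (1 - rho) * CN_n) / (rho * m)

with CN_t = major + minor the tumor total copy number and CN_n the normal
copy number at the locus (2 for autosomes).  The multiplicity ``m`` is not
observed; it is chosen from 1..major as the value whose implied CCF is
closest to the admissible [0, 1] interval.

Mutations are then grouped into clones by one-dimensional model-based
clustering of their CCFs.  When read counts are available the likelihood is
binomial on alt_count out of depth, with each mutation's success probability
a known linear map of the clone CCF (through its purity/copy-number
conversion factor); otherwise a Gaussian mixture on the point CCF estimates
is used.  The number of clones is selected by BIC.  This is a deterministic
stand-in for MCMC-based subclonal reconstruction: downstream scoring needs
only the partition and the clone CCFs, and an import path for externally
computed assignments is provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, special
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.mixture import GaussianMixture
from sklearn.utils.validation import check_is_fitted

from .variants import NON_SILENT_EFFECTS, Effect

__all__ = [
    "SomaticMutation",
    "CloneCluster",
    "estimate_ccf",
    "expected_vaf",
    "CCFClusterer",
    "cluster_mutations",
    "accept_precomputed_clusters",
    "default_purity",
]


@dataclass
class SomaticMutation:
    """A passed somatic call with VAF, copy number, multiplicity and CCF."""

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    effect: Effect
    vaf: float
    alt_count: int | None = None
    depth: int | None = None
    cn_major: int = 1
    cn_minor: int = 1
    multiplicity: int = 1
    ccf: float | None = None
    is_neoantigenic: bool = False
    n_epitopes: int = 0
    cluster_id: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf must be in [0,1], got {self.vaf} for {self.id}")
        if self.cn_major < 0 or self.cn_minor < 0:
            raise ValueError(f"copy numbers must be >= 0 for {self.id}")
        if not 1 <= self.multiplicity <= max(self.cn_major, 1):
            raise ValueError(
                f"multiplicity {self.multiplicity} outside 1..max(cn_major,1) for {self.id}"
            )
        if self.ccf is not None and not 0.0 <= self.ccf <= 1.0:
            raise ValueError(f"ccf must be in [0,1], got {self.ccf} for {self.id}")
        if self.is_neoantigenic and not self.is_non_silent:
            raise ValueError(f"silent/noncoding mutation {self.id} cannot be neoantigenic")
        if self.is_neoantigenic != (self.n_epitopes >= 1):
            raise ValueError(
                f"is_neoantigenic must equal (n_epitopes >= 1) for {self.id}"
            )

    @property
    def is_non_silent(self) -> bool:
        return self.effect in NON_SILENT_EFFECTS


@dataclass
class CloneCluster:
    """A clone: its cellular prevalence, member mutations and editing tallies.

    ``n_neoantigen`` counts member mutations bearing at least one predicted
    HLA-I binder; ``n_epitopes`` counts the predicted peptide-allele binders
    themselves (the alternative neoantigen-load unit).
    """

    cluster_id: int
    ccf: float
    member_ids: list[str] = field(default_factory=list)
    n_nonsilent: int = 0
    n_neoantigen: int = 0
    n_epitopes: int = 0
    editing_score: float | None = None
    stage: str | None = None  # "elimination" | "escape"

    def __post_init__(self) -> None:
        if not 0.0 <= self.ccf <= 1.0:
            raise ValueError(f"clone ccf must be in [0,1], got {self.ccf}")
        if min(self.n_nonsilent, self.n_neoantigen, self.n_epitopes) < 0:
            raise ValueError("clone tallies must be non-negative")
        if not self.n_neoantigen <= self.n_nonsilent:
            raise ValueError(
                f"expected n_neoantigen <= n_nonsilent, got "
                f"{self.n_neoantigen} > {self.n_nonsilent}"
            )
        if self.member_ids and self.n_nonsilent > len(self.member_ids):
            raise ValueError("n_nonsilent exceeds the number of member mutations")
        if self.n_epitopes < self.n_neoantigen:
            raise ValueError("n_epitopes must be >= n_neoantigen (>=1 binder each)")


def _vaf_conversion_factor(
    purity: float, cn_major: int, cn_minor: int, multiplicity: int, normal_cn: int
) -> float:
    """Factor c such that expected VAF = c * CCF."""
    cn_t = cn_major + cn_minor
    return purity * multiplicity / (purity * cn_t + (1.0 - purity) * normal_cn)


def expected_vaf(
    ccf: float,
    purity: float,
    cn_major: int = 1,
    cn_minor: int = 1,
    multiplicity: int = 1,
    normal_cn: int = 2,
) -> float:
    """Expected variant allele fraction of a mutation at the given CCF."""
    return ccf * _vaf_conversion_factor(purity, cn_major, cn_minor, multiplicity, normal_cn)


def estimate_ccf(
    vaf: float,
    purity: float,
    cn_major: int,
    cn_minor: int,
    normal_cn: int = 2,
) -> tuple[int, float]:
    """Invert VAF to (multiplicity, CCF) given purity and allele-specific copy number.

    Candidate multiplicities m in 1..cn_major are scanned; the chosen m is the
    one whose implied CCF is closest to [0, 1] (an implied CCF <= 1 is
    preferred, with the largest such m on ties).  The returned CCF is clipped
    to [0, 1].

    Raises
    ------
    ValueError
        If purity is 0 (CCF undefined) or inputs are out of range.
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity must be in (0,1], got {purity}")
    if not 0.0 <= vaf <= 1.0:
        raise ValueError(f"vaf must be in [0,1], got {vaf}")
    if cn_major < 1:
        raise ValueError(f"cn_major must be >= 1, got {cn_major}")
    if normal_cn not in (1, 2):
        raise ValueError(f"normal_cn must be 1 or 2, got {normal_cn}")
    cn_t = cn_major + cn_minor
    denom_base = purity * cn_t + (1.0 - purity) * normal_cn
    best: tuple[float, int] | None = None  # (distance to [0,1], -m)
    best_m, best_ccf = 1, 0.0
    for m in range(1, cn_major + 1):
        ccf_m = vaf * denom_base / (purity * m)
        dist = max(0.0, ccf_m - 1.0)
        key = (dist, -m)
        if best is None or key < best:
            best = key
            best_m, best_ccf = m, ccf_m
    return best_m, float(np.clip(best_ccf, 0.0, 1.0))


def default_purity(vafs: Sequence[float]) -> float:
    """Fallback purity when no estimate is available: 2x the 95th VAF percentile, capped at 1.

    Assumes a diploid genome where clonal heterozygous mutations sit at
    VAF = purity / 2.
    """
    if len(vafs) == 0:
        raise ValueError("cannot estimate purity from an empty VAF list")
    return float(min(1.0, 2.0 * np.percentile(np.asarray(vafs, dtype=float), 95)))


class CCFClusterer(BaseEstimator, ClusterMixin):
    """One-dimensional model-based clustering of mutation CCFs.

    Fits mixtures with 1..max_clusters components and keeps the one with the
    lowest BIC (ties broken toward fewer clusters).  With read counts the
    component likelihood for mutation j in clone k is
    Binomial(alt_j | depth_j, c_j * phi_k) where c_j is the mutation's
    VAF-per-CCF conversion factor and phi_k the clone CCF; without counts a
    Gaussian mixture on the point CCF estimates is used.

    Parameters
    ----------
    max_clusters : int, default=6
        Largest number of clones considered.
    random_state : int, default=0
        Seed for mixture initialisation; results are deterministic given it.
    max_iter : int, default=200
        EM iteration cap for the binomial mixture.
    tol : float, default=1e-6
        EM convergence tolerance on the mean log-likelihood.

    Attributes
    ----------
    n_clusters_ : int
        Selected number of clones.
    cluster_ccfs_ : ndarray of shape (n_clusters_,)
        Fitted clone CCFs, sorted descending.
    labels_ : ndarray of shape (n_samples,)
        Clone index (0-based, 0 = highest CCF) per mutation.
    weights_ : ndarray of shape (n_clusters_,)
        Mixture weights.
    bic_ : dict[int, float]
        BIC per candidate cluster count.
    """

    def __init__(
        self,
        max_clusters: int = 6,
        random_state: int = 0,
        max_iter: int = 200,
        tol: float = 1e-6,
    ) -> None:
        self.max_clusters = max_clusters
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None, *, alt=None, depth=None, conversion=None):
        """Fit the mixture.

        Parameters
        ----------
        X : array-like of shape (n_samples,) or (n_samples, 1)
            Point CCF estimates.
        alt, depth : array-like of shape (n_samples,), optional
            Mutant and total read counts; when both are given the binomial
            likelihood is used.
        conversion : array-like, optional
            Per-mutation VAF-per-CCF factors c_j; defaults to alt/(depth*ccf)
            consistency or 0.5 (diploid, full purity) where ccf is 0.
        """
        ccf = np.asarray(X, dtype=float).reshape(-1)
        n = ccf.size
        if n == 0:
            raise ValueError("cannot cluster zero mutations")
        if self.max_clusters < 1:
            raise ValueError(f"max_clusters must be >= 1, got {self.max_clusters}")
        n_unique = np.unique(ccf).size
        kmax = max(1, min(self.max_clusters, n_unique))
        if n == 1 or n_unique == 1:
            self.bic_ = {1: 0.0}
            self.n_clusters_ = 1
            self.cluster_ccfs_ = np.array([float(np.median(ccf))])
            self.weights_ = np.array([1.0])
            self.labels_ = np.zeros(n, dtype=int)
            return self
        if alt is not None and depth is not None:
            alt = np.asarray(alt, dtype=float)
            depth = np.asarray(depth, dtype=float)
            if conversion is None:
                # infer c_j from observed vaf and point ccf; fall back to 1/2
                with np.errstate(divide="ignore", invalid="ignore"):
                    c = np.where(ccf > 0, (alt / np.maximum(depth, 1.0)) / np.maximum(ccf, 1e-12), 0.5)
                c = np.clip(c, 1e-6, 1.0)
            else:
                c = np.asarray(conversion, dtype=float)
            fits = [self._fit_binomial_k(ccf, alt, depth, c, k) for k in range(1, kmax + 1)]
        else:
            fits = [self._fit_gaussian_k(ccf, k) for k in range(1, kmax + 1)]
        self.bic_ = {k + 1: f[0] for k, f in enumerate(fits)}
        # strict < keeps the smaller k on BIC ties
        best_k = min(self.bic_, key=lambda k: (self.bic_[k], k))
        _, phis, weights, labels = fits[best_k - 1]
        order = np.argsort(-phis)
        relabel = np.empty_like(order)
        relabel[order] = np.arange(order.size)
        self.n_clusters_ = int(best_k)
        self.cluster_ccfs_ = phis[order]
        self.weights_ = weights[order]
        self.labels_ = relabel[labels]
        return self

    def fit_predict(self, X, y=None, **kwargs):
        return self.fit(X, **kwargs).labels_

    def predict(self, X):
        """Assign new point CCFs to the nearest fitted clone CCF."""
        check_is_fitted(self, "cluster_ccfs_")
        ccf = np.asarray(X, dtype=float).reshape(-1)
        return np.argmin(np.abs(ccf[:, None] - self.cluster_ccfs_[None, :]), axis=1)

    # -- internal fits ---------------------------------------------------

    def _fit_gaussian_k(self, ccf, k):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="spherical",
            random_state=self.random_state,
            n_init=3,
            reg_covar=1e-6,
        ).fit(ccf.reshape(-1, 1))
        labels = gm.predict(ccf.reshape(-1, 1))
        return (
            float(gm.bic(ccf.reshape(-1, 1))),
            gm.means_.reshape(-1).clip(0.0, 1.0),
            gm.weights_,
            labels,
        )

    def _fit_binomial_k(self, ccf, alt, depth, c, k):
        n = ccf.size
        # deterministic quantile initialisation of the clone CCFs
        qs = (np.arange(k) + 0.5) / k
        phi = np.quantile(ccf, qs[::-1])[::-1]
        phi = np.clip(np.sort(phi), 1e-4, 1.0)
        w = np.full(k, 1.0 / k)
        ll_prev = -np.inf
        ll = ll_prev
        resp = np.full((n, k), 1.0 / k)
        for _ in range(self.max_iter):
            logp = self._binom_loglik(alt, depth, c, phi) + np.log(np.maximum(w, 1e-300))
            norm = special.logsumexp(logp, axis=1)
            resp = np.exp(logp - norm[:, None])
            ll = float(norm.mean())
            if abs(ll - ll_prev) < self.tol:
                break
            ll_prev = ll
            w = resp.mean(axis=0)
            for j in range(k):
                phi[j] = self._mstep_phi(alt, depth, c, resp[:, j], phi[j])
        total_ll = float(ll * n)
        n_params = 2 * k - 1
        bic = -2.0 * total_ll + n_params * np.log(n)
        labels = np.argmax(resp, axis=1)
        return bic, phi.copy(), w.copy(), labels

    @staticmethod
    def _binom_loglik(alt, depth, c, phi):
        p = np.clip(c[:, None] * phi[None, :], 1e-9, 1.0 - 1e-9)
        return alt[:, None] * np.log(p) + (depth - alt)[:, None] * np.log1p(-p)

    @staticmethod
    def _mstep_phi(alt, depth, c, w, phi0):
        if w.sum() < 1e-12:
            return phi0

        def neg_q(phi):
            p = np.clip(c * phi, 1e-9, 1.0 - 1e-9)
            return -float(np.sum(w * (alt * np.log(p) + (depth - alt) * np.log1p(-p))))

        res = optimize.minimize_scalar(neg_q, bounds=(1e-6, 1.0), method="bounded")
        return float(res.x)


def _build_clusters(
    mutations: Sequence[SomaticMutation], labels: Sequence
) -> list[CloneCluster]:
    """Group mutations by label; order clusters by descending median CCF, id 1 = highest."""
    groups: dict = {}
    for mut, lab in zip(mutations, labels):
        groups.setdefault(lab, []).append(mut)
    summaries = []
    for lab, members in groups.items():
        med_ccf = float(np.median([m.ccf for m in members]))
        summaries.append((med_ccf, lab, members))
    summaries.sort(key=lambda t: (-t[0], str(t[1])))
    clusters: list[CloneCluster] = []
    for new_id, (med_ccf, _lab, members) in enumerate(summaries, start=1):
        nonsilent = [m for m in members if m.is_non_silent]
        clusters.append(
            CloneCluster(
                cluster_id=new_id,
                ccf=med_ccf,
                member_ids=[m.id for m in members],
                n_nonsilent=len(nonsilent),
                n_neoantigen=sum(1 for m in nonsilent if m.is_neoantigenic),
                n_epitopes=sum(m.n_epitopes for m in nonsilent),
            )
        )
        for m in members:
            m.cluster_id = new_id
    return clusters


def cluster_mutations(
    mutations: Sequence[SomaticMutation],
    max_clusters: int = 6,
    seed: int = 0,
) -> list[CloneCluster]:
    """Partition mutations into clones by their CCFs.

    Every mutation must carry a ``ccf``.  Silent and non-coding mutations
    participate in the clustering (they inform clone structure) but only
    non-silent ones enter the clone's ``n_nonsilent`` tally.  Clone CCF is
    the median member CCF; clusters are ordered descending with id 1 the
    highest.  ``mutations`` have their ``cluster_id`` set in place.
    """
    if len(mutations) == 0:
        raise ValueError("cannot cluster an empty mutation list")
    missing = [m.id for m in mutations if m.ccf is None]
    if missing:
        raise ValueError(f"mutations without CCF: {missing[:5]}")
    ccfs = np.array([m.ccf for m in mutations])
    have_counts = all(m.alt_count is not None and m.depth is not None for m in mutations)
    clf = CCFClusterer(max_clusters=max_clusters, random_state=seed)
    if have_counts:
        labels = clf.fit_predict(
            ccfs,
            alt=[m.alt_count for m in mutations],
            depth=[m.depth for m in mutations],
        )
    else:
        labels = clf.fit_predict(ccfs)
    return _build_clusters(mutations, labels)


def accept_precomputed_clusters(
    mutations: Sequence[SomaticMutation],
    assignments: Mapping[str, object],
) -> list[CloneCluster]:
    """Build CloneCluster records from externally computed clone labels.

    ``assignments`` maps mutation id to an arbitrary cluster label.  The same
    ordering and CCF conventions as :func:`cluster_mutations` apply.
    """
    missing = [m.id for m in mutations if m.id not in assignments]
    if missing:
        raise KeyError(f"mutations missing from assignments: {missing}")
    labels = [assignments[m.id] for m in mutations]
    return _build_clusters(mutations, labels)
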