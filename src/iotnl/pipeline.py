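"""Top-level pipeline: filter -> CCF/cluster -> score -> cohort statistics.

`run_pipeline` chains the stages on file inputs and writes TSV/JSON outputs
plus a manifest (package version, configuration hash, seed), so a rerun
with the same configuration is reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict, field
from pathlib import Path

import pandas as pd

from . import __version__
from .clonal import cluster_mutations, default_purity, estimate_ccf
from .io import (
    annotate_neoantigens,
    attach_copy_number,
    build_cohort_table,
    read_clinical_table,
    read_cnv_segments,
    read_epitope_table,
    read_mutation_tsv,
    write_clusters_json,
    write_mutation_tsv,
    write_scores_tsv,
)
from .scoring import DEFAULT_EDITING_CUTOFF, compute_iotnl, compute_tmb
from .stats import evaluate_dichotomy, optimize_editing_cutoff

log = logging.getLogger("iotnl")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Paths and options for one pipeline run."""

    mutations_path: str
    out_dir: str
    cnv_path: str | None = None
    purity: float | None = None
    purity_table_path: str | None = None
    epitopes_path: str | None = None
    clinical_path: str | None = None
    editing_cutoff: float = DEFAULT_EDITING_CUTOFF
    optimize_cutoff: bool = False
    grid_start: float = 0.5
    grid_stop: float = 1.5
    grid_step: float = 0.1
    optimize_label: str = "ORR"
    count_unit: str = "mutation"
    rank_cutoff: float = 2.0
    affinity_cutoff_nm: float = 500.0
    region_mb: float = 30.0
    max_clusters: int = 6
    seed: int = 0
    endpoint: str = "PFS"

    def __post_init__(self) -> None:
        if self.grid_start > self.grid_stop or self.grid_step <= 0:
            raise ValueError("grid must satisfy start <= stop and step > 0")
        if self.region_mb <= 0:
            raise ValueError("region_mb must be > 0")

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    scores: pd.DataFrame
    clusters_by_patient: dict
    cohort: pd.DataFrame | None = None
    dichotomy: dict | None = None
    best_cutoff: float | None = None
    auc_per_cutoff: dict | None = None
    manifest: dict = field(default_factory=dict)
    fallback_purity_patients: list = field(default_factory=list)


def _patient_groups(mutations) -> dict[str, list]:
    groups: dict[str, list] = {}
    for m in mutations:
        pid = m.id.split(":", 1)[0] if ":" in m.id else "sample1"
        groups.setdefault(pid, []).append(m)
    return groups


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full scoring pipeline on file inputs.

    Mutations are read from a MAF-like TSV (mutation ids of the form
    ``patient:variant`` group rows into patients; otherwise the table is a
    single patient).  Per-patient stages: copy-number attachment, purity
    resolution (explicit scalar, per-sample table, or the diploid fallback
    from the VAF distribution), CCF estimation, clone clustering, epitope
    annotation and ioTNL scoring.  With a clinical table the cohort
    statistics (and optionally the editing-cutoff grid search) run at the
    end.
    """
    t0 = time.monotonic()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mutations = read_mutation_tsv(config.mutations_path)
    if not mutations:
        raise ValueError(f"stage=read: no mutations in {config.mutations_path}")
    if config.cnv_path:
        attach_copy_number(mutations, read_cnv_segments(config.cnv_path))
    if config.epitopes_path:
        annotate_neoantigens(
            mutations,
            read_epitope_table(config.epitopes_path),
            rank_cutoff=config.rank_cutoff,
            affinity_cutoff_nm=config.affinity_cutoff_nm,
        )
    purity_table = None
    if config.purity_table_path:
        purity_table = pd.read_csv(config.purity_table_path, sep="\t").set_index("patient_id")

    groups = _patient_groups(mutations)
    clusters_by_patient: dict = {}
    fallback_patients: list[str] = []
    for pid, muts in sorted(groups.items()):
        try:
            if purity_table is not None and pid in purity_table.index:
                purity = float(purity_table.loc[pid, "purity"])
            elif config.purity is not None:
                purity = config.purity
            else:
                purity = default_purity([m.vaf for m in muts])
                fallback_patients.append(pid)
            for m in muts:
                m.multiplicity, m.ccf = estimate_ccf(m.vaf, purity, m.cn_major, m.cn_minor)
            clusters_by_patient[pid] = cluster_mutations(
                muts, max_clusters=config.max_clusters, seed=config.seed
            )
        except Exception as err:
            raise RuntimeError(f"stage=cluster patient={pid}: {err}") from err
        log.info("clustered %s: %d mutations, %d clones", pid, len(muts),
                 len(clusters_by_patient[pid]))

    cohort = None
    dichotomy = None
    best_cutoff = None
    auc_per_cutoff = None
    cutoff = config.editing_cutoff

    def _score_all(cut: float) -> pd.DataFrame:
        rows = []
        for pid, clusters in sorted(clusters_by_patient.items()):
            s = compute_iotnl(
                clusters, cut, patient_id=pid,
                tmb=compute_tmb(groups[pid], config.region_mb),
                count_unit=config.count_unit,
            )
            rows.append({"patient_id": pid, "tnl": s.tnl, "tmb": s.tmb,
                         "iotnl": s.iotnl, "log10_iotnl": s.log10_iotnl,
                         "n_elimination": s.n_elimination, "n_escape": s.n_escape})
        return pd.DataFrame(rows)

    clinical = read_clinical_table(config.clinical_path) if config.clinical_path else None
    if config.optimize_cutoff:
        if clinical is None:
            raise ValueError("stage=optimize: cutoff optimization needs a clinical table")
        best_cutoff, auc_per_cutoff = optimize_editing_cutoff(
            lambda cut: build_cohort_table(_score_all(cut), clinical),
            grid_start=config.grid_start, grid_stop=config.grid_stop,
            grid_step=config.grid_step, label=config.optimize_label,
        )
        cutoff = best_cutoff
    scores = _score_all(cutoff)
    # refresh clone stage labels at the final cutoff
    for pid, clusters in clusters_by_patient.items():
        compute_iotnl(clusters, cutoff, patient_id=pid, count_unit=config.count_unit)
    if clinical is not None:
        cohort = build_cohort_table(scores, clinical)
        time_col = "pfs_days" if config.endpoint == "PFS" else "os_days"
        event_col = "pfs_event" if config.endpoint == "PFS" else "os_event"
        res = evaluate_dichotomy(
            cohort,
            time_col=time_col if time_col in cohort.columns else None,
            event_col=event_col if event_col in cohort.columns else None,
        )
        dichotomy = res.to_dict()

    manifest = {
        "package": "iotnl",
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "editing_cutoff_used": cutoff,
        "best_cutoff": best_cutoff,
        "n_patients": len(groups),
        "fallback_purity_patients": fallback_patients,
        "runtime_s": round(time.monotonic() - t0, 3),
    }
    scores.to_csv(out_dir / "patient_scores.tsv", sep="\t", index=False)
    write_mutation_tsv(mutations, out_dir / "mutations_with_ccf.tsv")
    write_clusters_json(clusters_by_patient, out_dir / "clusters.json")
    if dichotomy is not None:
        (out_dir / "dichotomy.json").write_text(json.dumps(dichotomy, indent=1, default=str))
    manifest_no_runtime = {k: v for k, v in manifest.items() if k != "runtime_s"}
    (out_dir / "manifest.json").write_text(json.dumps(manifest_no_runtime, indent=1))
    return PipelineResult(
        scores=scores,
        clusters_by_patient=clusters_by_patient,
        cohort=cohort,
        dichotomy=dichotomy,
        best_cutoff=best_cutoff,
        auc_per_cutoff=auc_per_cutoff,
        manifest=manifest,
        fallback_purity_patients=fallback_patients,
    )
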