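"""Readers and writers for the table dialects the pipeline exchanges.

TSV is the canonical interchange format, with MAF-like column names where
standard ones exist (Chromosome, Start_Position, Reference_Allele,
Tumor_Seq_Allele2, Variant_Classification, t_depth, t_alt_count, ...).
Read-level evidence travels as semicolon-separated quality lists in extra
columns.  VCF 4.x reading (AD/DP-style fields via cyvcf2) is a convenience
path.  All genomic coordinates are 1-based inclusive on read and write;
insertions are anchored at the base before the inserted sequence.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .clonal import CloneCluster, SomaticMutation
from .scoring import PatientScores
from .variants import CandidateVariant, FilterReport

__all__ = [
    "read_candidate_tsv",
    "write_candidate_tsv",
    "read_vcf_candidates",
    "read_mutation_tsv",
    "write_mutation_tsv",
    "read_cnv_segments",
    "attach_copy_number",
    "read_epitope_table",
    "annotate_neoantigens",
    "read_clinical_table",
    "build_cohort_table",
    "write_clusters_json",
    "read_clusters_json",
    "write_scores_tsv",
]

# MAF Variant_Classification -> internal effect vocabulary
_MAF_EFFECT = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
    "Frame_Shift_Ins": "frameshift_indel",
    "Frame_Shift_Del": "frameshift_indel",
    "In_Frame_Ins": "inframe_indel",
    "In_Frame_Del": "inframe_indel",
    "Splice_Site": "splice",
    "Silent": "silent",
}
_EFFECTS = {"missense", "nonsense", "frameshift_indel", "inframe_indel",
            "splice", "silent", "noncoding"}
_MAF_VTYPE = {"SNP": "SNV", "INS": "insertion", "DEL": "deletion",
              "SNV": "SNV", "insertion": "insertion", "deletion": "deletion"}

_CANDIDATE_REQUIRED = [
    "Chromosome", "Start_Position", "Reference_Allele", "Tumor_Seq_Allele2",
    "Variant_Type", "Variant_Classification",
    "t_depth", "t_alt_count", "n_depth", "n_alt_count",
]


def _effect(value: str, row: int) -> str:
    eff = _MAF_EFFECT.get(value, value)
    if eff not in _EFFECTS:
        eff = "noncoding"
    return eff


def _parse_list(cell) -> list[float]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return []
    return [float(x) for x in str(cell).split(";") if x != ""]


def _fmt_list(values: Iterable[float]) -> str:
    return ";".join(f"{v:g}" for v in values)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def read_candidate_tsv(path) -> list[CandidateVariant]:
    """Read candidate variants (with read-level evidence) from a MAF-like TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"Chromosome": str})
    _require_columns(df, _CANDIDATE_REQUIRED, path)
    out: list[CandidateVariant] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            out.append(
                CandidateVariant(
                    chrom=str(row.Chromosome),
                    pos=int(row.Start_Position),
                    ref=str(row.Reference_Allele),
                    alt=str(row.Tumor_Seq_Allele2),
                    variant_class=_MAF_VTYPE[str(row.Variant_Type)],
                    effect=_effect(str(row.Variant_Classification), i),
                    tumor_depth=int(row.t_depth),
                    tumor_alt_count=int(row.t_alt_count),
                    normal_depth=int(row.n_depth),
                    normal_alt_count=int(row.n_alt_count),
                    mutant_mapqs=_parse_list(getattr(row, "mutant_mapqs", None)),
                    mutant_baseqs=_parse_list(getattr(row, "mutant_baseqs", None)),
                    mutant_end_distances=_parse_list(getattr(row, "mutant_end_distances", None)),
                    ref_end_distances=_parse_list(getattr(row, "ref_end_distances", None)),
                    germline_flag=bool(getattr(row, "germline_flag", False)),
                )
            )
        except (ValueError, KeyError) as err:
            raise ValueError(f"{path}: malformed row {i}: {err}") from err
    return out


def write_candidate_tsv(candidates: Sequence[CandidateVariant], path) -> None:
    rows = []
    for v in candidates:
        rows.append(
            {
                "Chromosome": v.chrom,
                "Start_Position": v.pos,
                "Reference_Allele": v.ref,
                "Tumor_Seq_Allele2": v.alt,
                "Variant_Type": {"SNV": "SNP", "insertion": "INS", "deletion": "DEL"}[v.variant_class],
                "Variant_Classification": v.effect,
                "t_depth": v.tumor_depth,
                "t_alt_count": v.tumor_alt_count,
                "n_depth": v.normal_depth,
                "n_alt_count": v.normal_alt_count,
                "mutant_mapqs": _fmt_list(v.mutant_mapqs),
                "mutant_baseqs": _fmt_list(v.mutant_baseqs),
                "mutant_end_distances": _fmt_list(v.mutant_end_distances),
                "ref_end_distances": _fmt_list(v.ref_end_distances),
                "germline_flag": v.germline_flag,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_vcf_candidates(path, tumor_sample: str | None = None,
                        normal_sample: str | None = None) -> list[CandidateVariant]:
    """Read candidates from a VCF with per-sample AD/DP fields (convenience path).

    The tumor and normal samples default to the first and second samples in
    the file.  Read-level quality lists are not representable in VCF, so
    the significance criteria will reject these candidates unless the lists
    are attached afterwards.
    """
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(samples) < 2 and (tumor_sample is None or normal_sample is None):
        raise ValueError(f"{path}: need tumor and normal samples in the VCF")
    t_idx = samples.index(tumor_sample) if tumor_sample else 0
    n_idx = samples.index(normal_sample) if normal_sample else 1
    out: list[CandidateVariant] = []
    for rec in vcf:
        ad = rec.format("AD")
        dp = rec.format("DP")
        alt = rec.ALT[0] if rec.ALT else ""
        if len(rec.REF) == len(alt) == 1:
            vclass = "SNV"
        elif len(alt) > len(rec.REF):
            vclass = "insertion"
        else:
            vclass = "deletion"
        out.append(
            CandidateVariant(
                chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=alt,
                variant_class=vclass, effect="noncoding",
                tumor_depth=int(dp[t_idx][0]), tumor_alt_count=int(ad[t_idx][1]),
                normal_depth=int(dp[n_idx][0]), normal_alt_count=int(ad[n_idx][1]),
            )
        )
    return out


_MUTATION_REQUIRED = [
    "mutation_id", "Chromosome", "Start_Position", "Reference_Allele",
    "Tumor_Seq_Allele2", "Variant_Classification", "vaf",
]


def read_mutation_tsv(path) -> list[SomaticMutation]:
    """Read passed somatic mutations from a MAF-like TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"Chromosome": str})
    _require_columns(df, _MUTATION_REQUIRED, path)
    out: list[SomaticMutation] = []

    def _opt_int(row, name):
        v = getattr(row, name, None)
        return None if v is None or (isinstance(v, float) and np.isnan(v)) else int(v)

    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            n_epi = _opt_int(row, "n_epitopes") or 0
            ccf = getattr(row, "ccf", None)
            if ccf is not None and np.isnan(ccf):
                ccf = None
            out.append(
                SomaticMutation(
                    id=str(row.mutation_id),
                    chrom=str(row.Chromosome),
                    pos=int(row.Start_Position),
                    ref=str(row.Reference_Allele),
                    alt=str(row.Tumor_Seq_Allele2),
                    effect=_effect(str(row.Variant_Classification), i),
                    vaf=float(row.vaf),
                    alt_count=_opt_int(row, "t_alt_count"),
                    depth=_opt_int(row, "t_depth"),
                    cn_major=_opt_int(row, "cn_major") or 1,
                    cn_minor=_opt_int(row, "cn_minor") if _opt_int(row, "cn_minor") is not None else 1,
                    multiplicity=_opt_int(row, "multiplicity") or 1,
                    ccf=None if ccf is None else float(ccf),
                    is_neoantigenic=n_epi >= 1,
                    n_epitopes=n_epi,
                )
            )
        except (ValueError, KeyError) as err:
            raise ValueError(f"{path}: malformed row {i}: {err}") from err
    return out


def write_mutation_tsv(mutations: Sequence[SomaticMutation], path) -> None:
    rows = []
    for m in mutations:
        rows.append(
            {
                "mutation_id": m.id,
                "Chromosome": m.chrom,
                "Start_Position": m.pos,
                "Reference_Allele": m.ref,
                "Tumor_Seq_Allele2": m.alt,
                "Variant_Classification": m.effect,
                "vaf": m.vaf,
                "t_alt_count": m.alt_count,
                "t_depth": m.depth,
                "cn_major": m.cn_major,
                "cn_minor": m.cn_minor,
                "multiplicity": m.multiplicity,
                "ccf": m.ccf,
                "n_epitopes": m.n_epitopes,
                "cluster_id": m.cluster_id,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_cnv_segments(path) -> pd.DataFrame:
    """Allele-specific copy-number segments: chrom, start, end, major, minor (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, ["chrom", "start", "end", "major", "minor"], path)
    return df


def attach_copy_number(
    mutations: Sequence[SomaticMutation], segments: pd.DataFrame
) -> list[SomaticMutation]:
    """Set each mutation's allele-specific copy number from overlapping segments.

    Positions not covered by any segment keep the diploid default (1, 1).
    """
    for m in mutations:
        hit = segments[
            (segments["chrom"] == m.chrom)
            & (segments["start"] <= m.pos)
            & (segments["end"] >= m.pos)
        ]
        if len(hit):
            m.cn_major = int(hit.iloc[0]["major"])
            m.cn_minor = int(hit.iloc[0]["minor"])
    return list(mutations)


def read_epitope_table(path) -> pd.DataFrame:
    """Predicted HLA-I binders per mutation: mutation_id, hla_allele, peptide, affinity_nM, rank_pct."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["mutation_id", "hla_allele", "peptide", "affinity_nM", "rank_pct"], path)
    return df


def annotate_neoantigens(
    mutations: Sequence[SomaticMutation],
    epitopes: pd.DataFrame,
    rank_cutoff: float = 2.0,
    affinity_cutoff_nm: float = 500.0,
    require_expressed: bool = False,
) -> list[SomaticMutation]:
    """Flag neoantigenic mutations from a predicted-binder table.

    A peptide-allele pair is a binder when %rank <= ``rank_cutoff`` or
    affinity <= ``affinity_cutoff_nm``.  With ``require_expressed`` an
    optional boolean ``expressed`` column masks binders on non-expressed
    mutations.  Binders on silent/non-coding mutations are ignored.
    """
    binders = epitopes[
        (epitopes["rank_pct"] <= rank_cutoff)
        | (epitopes["affinity_nM"] <= affinity_cutoff_nm)
    ]
    if require_expressed and "expressed" in binders.columns:
        binders = binders[binders["expressed"].astype(bool)]
    counts = binders.groupby("mutation_id").size()
    for m in mutations:
        n = int(counts.get(m.id, 0)) if m.is_non_silent else 0
        m.n_epitopes = n
        m.is_neoantigenic = n >= 1
    return list(mutations)


def read_clinical_table(path) -> pd.DataFrame:
    """Clinical TSV: patient_id, response, dcb, pfs_days, pfs_event, os_days, os_event."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["patient_id", "response"], path)
    bad = ~df["response"].isin(["CR", "PR", "SD", "PD", "NE"])
    if bad.any():
        row = int(np.where(bad)[0][0]) + 1
        raise ValueError(f"{path}: row {row}: unknown response {df['response'][bad].iloc[0]!r}")
    return df


def build_cohort_table(scores: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """Join per-patient scores to clinical outcomes and derive ORR/DCB labels."""
    from .stats import orr_label

    merged = scores.merge(clinical, on="patient_id", how="inner", validate="one_to_one")
    merged["orr_label"] = merged["response"].map(orr_label)
    if "dcb" in merged.columns and "dcb_label" not in merged.columns:
        merged["dcb_label"] = merged["dcb"].fillna("NE")
    return merged


def write_clusters_json(
    clusters_by_patient: dict[str, Sequence[CloneCluster]], path,
    reports: dict | None = None,
) -> None:
    payload = {
        pid: [
            {
                "cluster_id": c.cluster_id,
                "ccf": c.ccf,
                "member_ids": list(c.member_ids),
                "n_nonsilent": c.n_nonsilent,
                "n_neoantigen": c.n_neoantigen,
                "n_epitopes": c.n_epitopes,
                "editing_score": c.editing_score,
                "stage": c.stage,
            }
            for c in clusters
        ]
        for pid, clusters in clusters_by_patient.items()
    }
    if reports:
        payload["_meta"] = reports
    Path(path).write_text(json.dumps(payload, indent=1))


def read_clusters_json(path) -> dict[str, list[CloneCluster]]:
    payload = json.loads(Path(path).read_text())
    out: dict[str, list[CloneCluster]] = {}
    for pid, clusters in payload.items():
        if pid == "_meta":
            continue
        out[pid] = [
            CloneCluster(
                cluster_id=c["cluster_id"], ccf=c["ccf"],
                member_ids=list(c.get("member_ids", [])),
                n_nonsilent=c["n_nonsilent"], n_neoantigen=c["n_neoantigen"],
                n_epitopes=c.get("n_epitopes", c["n_neoantigen"]),
                editing_score=c.get("editing_score"), stage=c.get("stage"),
            )
            for c in clusters
        ]
    return out


def write_scores_tsv(scores: Sequence[PatientScores], path) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "patient_id": s.patient_id,
                "tnl": s.tnl,
                "tmb": s.tmb,
                "iotnl": s.iotnl,
                "log10_iotnl": s.log10_iotnl,
                "n_elimination": s.n_elimination,
                "n_escape": s.n_escape,
            }
            for s in scores
        ]
    )
    df.to_csv(path, sep="\t", index=False)
    return df
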