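"""End-to-end orchestration of the three-library analysis.

Runs the two DE contrasts (grazing response: TG vs TU; differential
tolerance: IG vs TG), gene-level DEG collapsing, per-ontology enrichment with
dual-context selection, candidate-pattern classification and the SNP
consistency filter, over either a simulated experiment or loaded inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Mapping

import pandas as pd

from . import de as de_mod
from . import enrichment as enr
from . import patterns as pat
from . import snp as snp_mod
from .io import AnnotationMap, CountTable, TranscriptSeq
from .simulate import SimulatedExperiment

__all__ = ["PipelineResult", "deg_gene_set", "run_pipeline"]


@dataclass
class PipelineResult:
    de_response: pd.DataFrame
    de_tolerance: pd.DataFrame
    enrichment: dict[str, dict[str, pd.DataFrame]]  # ontology -> contrast -> table
    selections: dict[str, pd.DataFrame]             # ontology -> dual-context table
    gene_calls: list[pat.GeneCall]
    candidates: pd.DataFrame
    snp_report: pd.DataFrame = field(default_factory=pd.DataFrame)


def deg_gene_set(de_df: pd.DataFrame, groups: Mapping[str, str]) -> set[str]:
    """Genes with at least one differentially expressed transcript."""
    tids = de_df.loc[de_df["is_de"], "transcript_id"]
    return {groups.get(t, t) for t in tids}


def run_pipeline(
    counts: CountTable | SimulatedExperiment,
    groups: Mapping[str, str] | None = None,
    annotations: Mapping[str, AnnotationMap] | None = None,
    sequences: Mapping[str, TranscriptSeq] | None = None,
    base_composition: pd.DataFrame | None = None,
    roles: Mapping[str, str] | None = None,
    fdr_threshold: float = de_mod.DEFAULT_FDR,
    lfc_threshold: float = de_mod.DEFAULT_LFC,
    alpha: float = enr.DEFAULT_ALPHA,
    snp_params: snp_mod.SnpCallingParams | None = None,
) -> PipelineResult:
    """Run every stage; pass a :class:`SimulatedExperiment` or explicit parts."""
    if isinstance(counts, SimulatedExperiment):
        exp = counts
        counts = exp.counts
        groups = exp.groups
        annotations = exp.annotations
        sequences = exp.sequences
        base_composition = exp.base_composition
        roles = exp.roles
    if groups is None or roles is None:
        raise ValueError("groups and roles are required")
    tu, tg, ig = (
        roles["tolerant_ungrazed"],
        roles["tolerant_grazed"],
        roles["intolerant_grazed"],
    )
    de_response = de_mod.de_table(counts, tu, tg, fdr_threshold, lfc_threshold)
    de_tolerance = de_mod.de_table(counts, tg, ig, fdr_threshold, lfc_threshold)
    degs_response = deg_gene_set(de_response, groups)
    degs_tolerance = deg_gene_set(de_tolerance, groups)

    enrichment: dict[str, dict[str, pd.DataFrame]] = {}
    selections: dict[str, pd.DataFrame] = {}
    for name, ann in (annotations or {}).items():
        resp = enr.enrich(ann, degs_response, contrast_label="response")
        tol = enr.enrich(ann, degs_tolerance, contrast_label="tolerance")
        enrichment[name] = {"response": resp, "tolerance": tol}
        selections[name] = enr.dual_context_select(resp, tol, alpha=alpha)

    profiles = pat.build_profiles(de_response, de_tolerance, groups)
    gene_calls = pat.classify_genes(profiles)

    cand_parts = []
    for name, ann in (annotations or {}).items():
        sel = selections[name]
        if sel["selected"].any():
            cand_parts.append(pat.intersect_candidates(gene_calls, sel, ann))
    if cand_parts:
        candidates = (
            pd.concat(cand_parts)
            .groupby(["gene_id", "pattern", "n_transcripts", "n_supporting"], as_index=False)
            .agg({"supporting_terms": lambda s: ";".join(sorted(set(";".join(s).split(";"))))})
            .sort_values("gene_id")
            .reset_index(drop=True)
        )
    else:
        candidates = pd.DataFrame(
            columns=["gene_id", "pattern", "n_transcripts", "n_supporting", "supporting_terms"]
        )

    if base_composition is not None and len(base_composition):
        snp_report = snp_mod.call_snps(base_composition, sequences or {}, dict(roles), snp_params)
    else:
        snp_report = pd.DataFrame()
    return PipelineResult(
        de_response=de_response,
        de_tolerance=de_tolerance,
        enrichment=enrichment,
        selections=selections,
        gene_calls=gene_calls,
        candidates=candidates,
        snp_report=snp_report,
    )
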