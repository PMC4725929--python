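"""Candidate-gene expression patterns across the three transcriptomes.

The three libraries are tolerant-ungrazed (TU), tolerant-grazed (TG) and
intolerant-grazed (IG). A transcript is a *suppressed tolerant-advantage*
candidate when grazing significantly suppresses it in the tolerant plants
(TG < TU) and the grazed intolerant plants express it at an even lower level
(IG < TG, also significant); an *upregulated tolerant-advantage* candidate
when grazing induces it (TG > TU) and the tolerant plants out-express the
intolerant ones (TG > IG). Gene-level calls require directional consistency
across a gene's isoforms: non-candidate isoforms are tolerated, opposite
candidate patterns veto the gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Iterable, Mapping

import pandas as pd

from .io import AnnotationMap

__all__ = [
    "SUPPRESSED",
    "UPREGULATED",
    "OTHER",
    "TranscriptProfile",
    "GeneCall",
    "classify_transcript",
    "aggregate_gene",
    "build_profiles",
    "classify_genes",
    "intersect_candidates",
]

SUPPRESSED = "suppressed_tolerant_advantage"
UPREGULATED = "upregulated_tolerant_advantage"
OTHER = "other"


@dataclass
class TranscriptProfile:
    """One transcript's FPKM triple and DE calls for the two contrasts.

    ``log2fc_response`` is TG over TU; ``log2fc_tolerance`` is IG over TG
    (so a negative tolerance fold change means the tolerant plants express
    more than the intolerant plants, both grazed).
    """

    transcript_id: str
    gene_id: str
    fpkm_tu: float
    fpkm_tg: float
    fpkm_ig: float
    de_response: bool
    log2fc_response: float
    de_tolerance: bool
    log2fc_tolerance: float


@dataclass
class GeneCall:
    gene_id: str
    pattern: str
    n_transcripts: int
    n_supporting: int


def classify_transcript(profile: TranscriptProfile) -> str:
    """Assign one of the three patterns to a transcript."""
    for flag in (profile.de_response, profile.de_tolerance):
        if flag is None:
            raise ValueError(f"{profile.transcript_id}: missing DE flag")
    tolerant_advantage = profile.de_tolerance and profile.log2fc_tolerance < 0
    if profile.de_response and profile.log2fc_response < 0 and tolerant_advantage:
        return SUPPRESSED
    if profile.de_response and profile.log2fc_response > 0 and tolerant_advantage:
        return UPREGULATED
    return OTHER


def aggregate_gene(profiles: Iterable[TranscriptProfile]) -> GeneCall:
    """Collapse a gene's isoform patterns into one consistent gene call."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles supplied")
    genes = {p.gene_id for p in profiles}
    if len(genes) != 1:
        raise ValueError(f"profiles from mixed genes: {sorted(genes)}")
    patterns = [classify_transcript(p) for p in profiles]
    n_sup = patterns.count(SUPPRESSED)
    n_up = patterns.count(UPREGULATED)
    if n_sup and n_up:
        pattern, supporting = OTHER, 0
    elif n_sup:
        pattern, supporting = SUPPRESSED, n_sup
    elif n_up:
        pattern, supporting = UPREGULATED, n_up
    else:
        pattern, supporting = OTHER, 0
    return GeneCall(genes.pop(), pattern, len(profiles), supporting)


def build_profiles(
    de_response: pd.DataFrame,
    de_tolerance: pd.DataFrame,
    groups: Mapping[str, str],
) -> list[TranscriptProfile]:
    """Join the two contrast tables into per-transcript profiles.

    ``de_response`` must be the TG-vs-TU contrast (TU baseline) and
    ``de_tolerance`` the IG-vs-TG contrast (TG baseline), as produced by
    :func:`grazetx.de.de_table`.
    """
    resp = de_response.set_index("transcript_id")
    tol = de_tolerance.set_index("transcript_id")
    common = resp.index.intersection(tol.index)
    profiles = []
    for tid in common:
        r = resp.loc[tid]
        t = tol.loc[tid]
        profiles.append(
            TranscriptProfile(
                transcript_id=tid,
                gene_id=groups.get(tid, tid),
                fpkm_tu=float(r["fpkm_a"]),
                fpkm_tg=float(r["fpkm_b"]),
                fpkm_ig=float(t["fpkm_b"]),
                de_response=bool(r["is_de"]),
                log2fc_response=float(r["log2fc"]),
                de_tolerance=bool(t["is_de"]),
                log2fc_tolerance=float(t["log2fc"]),
            )
        )
    return profiles


def classify_genes(profiles: Iterable[TranscriptProfile]) -> list[GeneCall]:
    """Group profiles by gene and aggregate, ordered by gene_id."""
    by_gene: dict[str, list[TranscriptProfile]] = {}
    for p in profiles:
        by_gene.setdefault(p.gene_id, []).append(p)
    return [aggregate_gene(by_gene[g]) for g in sorted(by_gene)]


def intersect_candidates(
    gene_calls: Iterable[GeneCall],
    selection: pd.DataFrame,
    annotation: AnnotationMap,
) -> pd.DataFrame:
    """Candidate genes: non-other pattern AND annotated to a selected term.

    ``selection`` is the output of
    :func:`grazetx.enrichment.dual_context_select`; only its selected rows
    count. Returns a table ordered by gene_id with the supporting terms
    listed.
    """
    if selection.empty:
        raise ValueError("empty dual-context selection")
    selected_terms = set(selection.loc[selection["selected"], "term_id"])
    gene_to_terms: dict[str, set[str]] = {}
    for term in selected_terms:
        for gene in annotation.terms.get(term, frozenset()):
            gene_to_terms.setdefault(gene, set()).add(term)
    rows = []
    for call in sorted(gene_calls, key=lambda c: c.gene_id):
        if call.pattern == OTHER:
            continue
        terms = gene_to_terms.get(call.gene_id)
        if terms:
            rows.append(
                (
                    call.gene_id,
                    call.pattern,
                    call.n_transcripts,
                    call.n_supporting,
                    ";".join(sorted(terms)),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "pattern", "n_transcripts", "n_supporting", "supporting_terms"],
    )
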