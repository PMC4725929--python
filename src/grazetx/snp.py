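"""IUPAC consensus calling, tolerance-consistency SNP filtering and coding
effect annotation.

A site is reported when the two tolerant libraries (grazed and ungrazed) agree
on a single base while the grazed intolerant library carries variation at that
position — either a different single base or a two-allele ambiguity code.
Positions are 1-based from the transcript 5' end; effects are annotated by
translating the affected codon with the standard genetic code.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Mapping

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .io import TranscriptSeq

__all__ = [
    "IUPAC_TWO_BASE",
    "NO_CALL",
    "SnpCallingParams",
    "iupac_call",
    "decode_iupac",
    "consistency_filter",
    "annotate_effect",
    "call_snps",
]

NO_CALL = "."

IUPAC_TWO_BASE = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}
_CODE_TO_BASES = {v: k for k, v in IUPAC_TWO_BASE.items()} | {b: frozenset(b) for b in "ACGT"}

REGION_5UTR = "5'UTR"
REGION_CDS = "CDS"
REGION_3UTR = "3'UTR"
REGION_NONCODING = "noncoding"


@dataclass
class SnpCallingParams:
    """Consensus-calling thresholds (declared defaults, config-exposed)."""

    min_count: int = 4        # minimum coverage to attempt a call
    min_frac: float = 0.2     # minimum allele frequency to retain an allele
    min_allele_count: int = 2  # minimum reads supporting a retained allele


def decode_iupac(code: str) -> frozenset[str]:
    """The set of bases a single-base or two-base IUPAC code stands for."""
    try:
        return _CODE_TO_BASES[code]
    except KeyError:
        raise ValueError(f"unsupported IUPAC code {code!r}") from None


def iupac_call(base_counts: Mapping[str, int], params: SnpCallingParams | None = None) -> str:
    """Call a single-base or two-base IUPAC consensus for one sample.

    Returns :data:`NO_CALL` when coverage is below ``min_count`` or when more
    than two alleles survive filtering with a tie preventing reduction to two.
    """
    params = params or SnpCallingParams()
    counts = {b: int(base_counts.get(b, 0)) for b in "ACGT"}
    total = sum(counts.values())
    if total < params.min_count:
        return NO_CALL
    retained = [
        (c, b)
        for b, c in counts.items()
        if c >= params.min_allele_count and c / total >= params.min_frac
    ]
    retained.sort(key=lambda t: (-t[0], t[1]))
    if not retained:
        return NO_CALL
    if len(retained) > 2:
        # drop lowest-frequency alleles; a tie at the cut is unresolvable
        if retained[1][0] == retained[2][0]:
            return NO_CALL
        retained = retained[:2]
    bases = frozenset(b for _, b in retained)
    if len(bases) == 1:
        return next(iter(bases))
    return IUPAC_TWO_BASE[bases]


def consistency_filter(
    calls: Mapping[str, str],
    tolerant_grazed: str = "TG",
    tolerant_ungrazed: str = "TU",
    intolerant_grazed: str = "IG",
) -> tuple[bool, str | None]:
    """Apply the monomorphic-tolerant / polymorphic-intolerant rule.

    ``calls`` maps sample roles to IUPAC codes (or :data:`NO_CALL`). Keeps a
    site iff both tolerant libraries carry the same single base and the
    intolerant library differs (a different single base or any two-base
    ambiguity code). Returns ``(keep, "ref:alt")`` with alt alleles sorted and
    ':'-joined.
    """
    try:
        tg = calls[tolerant_grazed]
        tu = calls[tolerant_ungrazed]
        ig = calls[intolerant_grazed]
    except KeyError as exc:
        raise ValueError(f"missing sample role {exc.args[0]!r}") from None
    if NO_CALL in (tg, tu, ig):
        return False, None
    if tg != tu or tg not in "ACGT":
        return False, None
    ref = tg
    ig_bases = decode_iupac(ig)
    if ig_bases == frozenset(ref):
        return False, None
    alts = sorted(ig_bases - {ref})
    if not alts:  # cannot happen: ig_bases != {ref} implies a novel allele
        return False, None
    return True, ":".join([ref] + alts)


def annotate_effect(
    transcript: TranscriptSeq,
    pos: int,
    ref_base: str,
    alt_bases: list[str],
) -> tuple[str, str]:
    """Region and amino-acid effect of substituting ``alt_bases`` at ``pos``.

    Returns ``(region, effect)``. UTR/noncoding sites report the region as the
    effect; CDS sites translate the affected codon per alternative allele and
    report ``synonymous`` or semicolon-joined ``From->To (allele)`` strings
    (stop codons rendered as ``X``). Raises if ``ref_base`` disagrees with the
    sequence.
    """
    seq = transcript.sequence
    if not (1 <= pos <= len(seq)):
        raise ValueError(f"{transcript.transcript_id}: position {pos} outside sequence")
    if seq[pos - 1] != ref_base:
        raise ValueError(
            f"{transcript.transcript_id}:{pos}: sequence has {seq[pos - 1]}, report says {ref_base}"
        )
    if transcript.cds is None:
        return REGION_NONCODING, REGION_NONCODING
    start, end = transcript.cds
    if pos < start:
        return REGION_5UTR, REGION_5UTR
    if pos > end:
        return REGION_3UTR, REGION_3UTR
    offset = pos - start
    codon_start = start + 3 * (offset // 3)
    within = offset % 3
    codon = seq[codon_start - 1 : codon_start + 2]
    ref_aa = str(Seq(codon).translate())
    parts = []
    any_nonsyn = False
    for alt in alt_bases:
        mutated = codon[:within] + alt + codon[within + 1 :]
        alt_aa = str(Seq(mutated).translate())
        if alt_aa == ref_aa:
            parts.append(("syn", alt))
        else:
            any_nonsyn = True
            parts.append((f"{_aa3(ref_aa)}->{_aa3(alt_aa)}", alt))
    if not any_nonsyn:
        return REGION_CDS, "synonymous"
    rendered = [
        (f"synonymous ({alt})" if label == "syn" else f"{label} ({alt})")
        for label, alt in parts
    ]
    return REGION_CDS, ";".join(rendered)


def _aa3(aa: str) -> str:
    return "X" if aa == "*" else seq3(aa)


def call_snps(
    base_comp: pd.DataFrame,
    sequences: Mapping[str, TranscriptSeq],
    roles: Mapping[str, str],
    params: SnpCallingParams | None = None,
) -> pd.DataFrame:
    """Run the full per-position SNP pipeline over a base-composition table.

    ``base_comp`` has columns transcript_id, pos, sample, nA, nC, nG, nT; one
    row per (transcript, pos, sample). ``roles`` maps the role names
    tolerant_grazed / tolerant_ungrazed / intolerant_grazed to sample ids.
    Returns the report of sites passing the consistency filter, with region
    and amino-acid effect where a sequence is available.
    """
    params = params or SnpCallingParams()
    required = {"tolerant_grazed", "tolerant_ungrazed", "intolerant_grazed"}
    if set(roles) != required:
        raise ValueError(f"roles must be exactly {sorted(required)}")
    rows = []
    for (tid, pos), grp in base_comp.groupby(["transcript_id", "pos"], sort=True):
        calls: dict[str, str] = {}
        for role, sample in roles.items():
            sub = grp[grp["sample"] == sample]
            if sub.empty:
                calls[role] = NO_CALL
            else:
                r = sub.iloc[0]
                calls[role] = iupac_call(
                    {"A": r["nA"], "C": r["nC"], "G": r["nG"], "T": r["nT"]}, params
                )
        keep, variant = consistency_filter(
            calls,
            tolerant_grazed="tolerant_grazed",
            tolerant_ungrazed="tolerant_ungrazed",
            intolerant_grazed="intolerant_grazed",
        )
        if not keep:
            continue
        ref, *alts = variant.split(":")
        if tid in sequences:
            region, effect = annotate_effect(sequences[tid], int(pos), ref, alts)
        else:
            region, effect = REGION_NONCODING, REGION_NONCODING
        rows.append(
            (
                tid,
                int(pos),
                ref,
                calls["tolerant_grazed"],
                calls["tolerant_ungrazed"],
                calls["intolerant_grazed"],
                variant,
                region,
                effect,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            "pos",
            "consensus_base",
            "call_tolerant_grazed",
            "call_tolerant_ungrazed",
            "call_intolerant_grazed",
            "variant",
            "region",
            "effect",
        ],
    )
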