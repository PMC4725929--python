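"""Tabular and sequence I/O for the three-library grazing-tolerance pipeline.

All tables are tab-separated UTF-8 with a single header line. Library totals
are *clean-read* totals supplied explicitly (they may exceed the sum of mapped
counts), carried on a leading ``#total_clean_reads`` comment line of the count
table. CDS coordinates are 1-based inclusive on the transcript's 5'->3' strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO

__all__ = [
    "CountTable",
    "AnnotationMap",
    "TranscriptSeq",
    "FormatError",
    "read_count_table",
    "write_count_table",
    "read_annotation",
    "write_annotation",
    "read_isoform_groups",
    "write_isoform_groups",
    "read_fasta_with_cds",
    "write_fasta_with_cds",
]


class FormatError(ValueError):
    """Raised when an input file violates the pipeline's format contracts."""


@dataclass
class CountTable:
    """Per-transcript read counts with lengths and library clean-read totals.

    ``counts`` is indexed by transcript_id with one integer column per sample;
    ``lengths`` holds transcript length in bp; ``totals`` maps sample id to the
    library's total clean reads (the N of the exact test, which is a
    library-level count and need not equal the mapped-count sum).
    """

    counts: pd.DataFrame
    lengths: pd.Series
    totals: dict[str, int]

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique()
            raise FormatError(f"duplicate transcript_id: {', '.join(map(str, dups[:5]))}")
        if list(self.counts.columns) != list(self.totals):
            raise FormatError("totals must name exactly the count-table samples, in order")
        if not all(int(v) > 0 for v in self.totals.values()):
            raise FormatError("library totals must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("negative count encountered")
        if not self.lengths.index.equals(self.counts.index):
            raise FormatError("lengths index must match counts index")
        if (self.lengths.to_numpy() <= 0).any():
            raise FormatError("transcript lengths must be positive")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.counts.index)


@dataclass
class AnnotationMap:
    """Flat term -> gene-set annotation for one ontology (e.g. GO, KEGG).

    The universe is the set of genes carrying at least one term in this
    ontology; it is the background N of the over-representation test.
    """

    name: str
    terms: dict[str, frozenset[str]]
    universe: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            if not genes:
                raise FormatError(f"term {term} has an empty gene set")
        derived = frozenset().union(*self.terms.values()) if self.terms else frozenset()
        if not self.universe:
            self.universe = derived
        elif not derived <= self.universe:
            raise FormatError("annotated genes outside the declared universe")


@dataclass
class TranscriptSeq:
    """A transcript sequence with an optional 1-based inclusive CDS interval."""

    transcript_id: str
    sequence: str
    cds: tuple[int, int] | None = None


def read_count_table(path: str | Path) -> CountTable:
    """Read a count table (``#total_clean_reads`` comment line + TSV body)."""
    path = Path(path)
    totals: dict[str, int] | None = None
    with path.open(encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith("#total_clean_reads"):
            raise FormatError(f"{path}: missing #total_clean_reads line")
        fields = first.split("\t")[1:]
        try:
            totals = {k: int(v) for k, v in (f.split("=", 1) for f in fields)}
        except ValueError as exc:
            raise FormatError(f"{path}: malformed totals line") from exc
        body = pd.read_csv(fh, sep="\t", dtype={"transcript_id": str})
    if "transcript_id" not in body.columns or "length_bp" not in body.columns:
        raise FormatError(f"{path}: header must contain transcript_id and length_bp")
    sample_cols = [c for c in body.columns if c not in ("transcript_id", "length_bp")]
    if set(sample_cols) != set(totals):
        raise FormatError(f"{path}: totals samples {sorted(totals)} != columns {sorted(sample_cols)}")
    for col in sample_cols + ["length_bp"]:
        vals = body[col]
        if not pd.api.types.is_integer_dtype(vals):
            raise FormatError(f"{path}: column {col} must be integer")
    counts = body.set_index("transcript_id")[sample_cols]
    lengths = body.set_index("transcript_id")["length_bp"]
    return CountTable(counts=counts, lengths=lengths, totals={s: totals[s] for s in sample_cols})


def write_count_table(table: CountTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        tot = "\t".join(f"{s}={table.totals[s]}" for s in table.sample_ids)
        fh.write(f"#total_clean_reads\t{tot}\n")
        out = table.counts.copy()
        out.insert(0, "length_bp", table.lengths)
        out.to_csv(fh, sep="\t", index_label="transcript_id")


def read_annotation(path: str | Path, name: str | None = None) -> AnnotationMap:
    """Read a two-column (gene_id, term_id) TSV into an :class:`AnnotationMap`."""
    path = Path(path)
    terms: dict[str, set[str]] = {}
    n_lines = 0
    with path.open(encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise FormatError(f"{path}: empty annotation file")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise FormatError(f"{path}:{lineno}: expected 'gene_id<TAB>term_id'")
            gene, term = parts
            terms.setdefault(term, set()).add(gene)
            n_lines += 1
    if n_lines == 0:
        raise FormatError(f"{path}: annotation file has no data lines")
    return AnnotationMap(
        name=name or path.stem,
        terms={t: frozenset(g) for t, g in terms.items()},
    )


def write_annotation(annotation: AnnotationMap, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("gene_id\tterm_id\n")
        for term in sorted(annotation.terms):
            for gene in sorted(annotation.terms[term]):
                fh.write(f"{gene}\t{term}\n")


def read_isoform_groups(path: str | Path) -> dict[str, str]:
    """Read the transcript_id -> gene_id grouping table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["transcript_id", "gene_id"]:
        raise FormatError(f"{path}: header must be 'transcript_id<TAB>gene_id'")
    if df["transcript_id"].duplicated().any():
        dup = df.loc[df["transcript_id"].duplicated(), "transcript_id"].iloc[0]
        raise FormatError(f"{path}: transcript {dup} grouped more than once")
    return dict(zip(df["transcript_id"], df["gene_id"]))


def write_isoform_groups(groups: Mapping[str, str], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("transcript_id\tgene_id\n")
        for tid in groups:
            fh.write(f"{tid}\t{groups[tid]}\n")


def read_fasta_with_cds(fasta_path: str | Path, cds_table_path: str | Path) -> dict[str, TranscriptSeq]:
    """Attach 1-based inclusive CDS intervals to FASTA transcript sequences.

    Transcripts absent from the CDS table are retained with ``cds=None``
    (reported downstream as noncoding). The CDS must lie within the sequence
    and have length divisible by 3.
    """
    cds_df = pd.read_csv(cds_table_path, sep="\t", dtype={"transcript_id": str})
    required = {"transcript_id", "cds_start", "cds_end"}
    if not required <= set(cds_df.columns):
        raise FormatError(f"{cds_table_path}: header must contain {sorted(required)}")
    cds_map = {
        row.transcript_id: (int(row.cds_start), int(row.cds_end))
        for row in cds_df.itertuples()
    }
    out: dict[str, TranscriptSeq] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper()
        cds = cds_map.get(rec.id)
        if cds is not None:
            start, end = cds
            if not (1 <= start <= end <= len(seq)):
                raise FormatError(f"{rec.id}: CDS {start}..{end} out of bounds for length {len(seq)}")
            if (end - start + 1) % 3 != 0:
                raise FormatError(f"{rec.id}: CDS length {end - start + 1} not divisible by 3")
        out[rec.id] = TranscriptSeq(transcript_id=rec.id, sequence=seq, cds=cds)
    return out


def write_fasta_with_cds(seqs: Mapping[str, TranscriptSeq], fasta_path: str | Path, cds_table_path: str | Path) -> None:
    with Path(fasta_path).open("w", encoding="utf-8") as fh:
        for tid, ts in seqs.items():
            fh.write(f">{tid}\n")
            for i in range(0, len(ts.sequence), 70):
                fh.write(ts.sequence[i : i + 70] + "\n")
    with Path(cds_table_path).open("w", encoding="utf-8") as fh:
        fh.write("transcript_id\tcds_start\tcds_end\n")
        for tid, ts in seqs.items():
            if ts.cds is not None:
                fh.write(f"{tid}\t{ts.cds[0]}\t{ts.cds[1]}\n")
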